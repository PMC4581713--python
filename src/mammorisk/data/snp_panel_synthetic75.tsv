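snp_id	risk_allele_freq	odds_ratio
snpSYN001	0.1049563586	1.080754768
snpSYN002	0.6610628326	1.059583068
snpSYN003	0.4428911374	1.02863493
snpSYN004	0.3238348754	1.058663656
snpSYN005	0.573117582	1.069046837
snpSYN006	0.8713464327	1.096814854
snpSYN007	0.3179997802	1.033835864
snpSYN008	0.5696940037	1.028610484
snpSYN009	0.4378962464	1.091300448
snpSYN010	0.6186830183	1.046324901
snpSYN011	0.3808585058	1.10098912
snpSYN012	0.7691458659	1.05889349
snpSYN013	0.4036738514	1.048243146
snpSYN014	0.8370264323	1.031127451
snpSYN015	0.7749696621	1.073268601
snpSYN016	0.3460548348	1.098354094
snpSYN017	0.2495060691	1.087459195
snpSYN018	0.4518743164	1.040194081
snpSYN019	0.811573239	1.016928954
snpSYN020	0.8408314578	1.018954775
snpSYN021	0.2791299001	1.102944911
snpSYN022	0.2314153036	1.028168674
snpSYN023	0.8316697953	1.044610611
snpSYN024	0.5548101469	1.078633178
snpSYN025	0.3061877591	1.038587474
snpSYN026	0.6806087722	1.027296767
snpSYN027	0.8113285156	1.022651623
snpSYN028	0.8321391673	1.038628448
snpSYN029	0.1026902947	1.090363242
snpSYN030	0.5923582871	1.028473793
snpSYN031	0.1862649718	1.083984321
snpSYN032	0.2140828966	1.073700879
snpSYN033	0.5822842305	1.037405313
snpSYN034	0.8450420054	1.084307439
snpSYN035	0.4427986529	1.037045401
snpSYN036	0.2499997041	1.100122763
snpSYN037	0.5541569557	1.089005356
snpSYN038	0.1513236169	1.038173563
snpSYN039	0.6485663406	1.065031806
snpSYN040	0.6850785709	1.057362942
snpSYN041	0.6480834641	1.068768709
snpSYN042	0.687610193	1.027123997
snpSYN043	0.5517588874	1.020911465
snpSYN044	0.6189694829	1.034254165
snpSYN045	0.5631633947	1.049428628
snpSYN046	0.5355212612	1.058723042
snpSYN047	0.6619244746	1.022924875
snpSYN048	0.6793151666	1.062283302
snpSYN049	0.4632742048	1.127631238
snpSYN050	0.376484866	1.078134931
snpSYN051	0.6646980458	1.022441834
snpSYN052	0.1865736788	1.071241415
snpSYN053	0.4660581598	1.252030526
snpSYN054	0.7952226817	1.025985841
snpSYN055	0.6496879236	1.063946404
snpSYN056	0.849761101	1.041758886
snpSYN057	0.7350648291	1.116217822
snpSYN058	0.6638713154	1.109314272
snpSYN059	0.5666079609	1.065267123
snpSYN060	0.7197136075	1.051736358
snpSYN061	0.8314647805	1.036015834
snpSYN062	0.2782549664	1.062503616
snpSYN063	0.8653075547	1.046419315
snpSYN064	0.8282718151	1.059696347
snpSYN065	0.2118175302	1.104025809
snpSYN066	0.6269122336	1.027729779
snpSYN067	0.8041608583	1.059407398
snpSYN068	0.4707143669	1.078586365
snpSYN069	0.5477684495	1.025245501
snpSYN070	0.7583613165	1.024080766
snpSYN071	0.5136519484	1.060812865
snpSYN072	0.4155683232	1.043646912
snpSYN073	0.6945532696	1.037285057
snpSYN074	0.7340081651	1.115288629
snpSYN075	0.1819970418	1.032684888
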
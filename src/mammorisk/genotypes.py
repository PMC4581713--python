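"""Case-status-conditional genotype simulation and the genetic risk score.

A panel of independent susceptibility SNPs is described by a risk-allele
frequency ``p`` and a per-allele odds ratio ``OR`` per locus. Genotypes of
unaffected women follow Hardy-Weinberg proportions ((1-p)^2, 2p(1-p), p^2);
genotypes of cases are drawn from the exponentially tilted distribution
``Q_g proportional to OR^g * P_g`` — the canonical log-additive per-allele
model. The genetic risk score (GRS) of a woman is
``sum_j log(OR_j) * g_j`` over the panel.

A consequence worth knowing: under this sampling scheme the case/non-case
odds given a genotype vector are proportional to ``exp(GRS)``, so a logistic
(or, for a rare disease, Cox) regression of case status on GRS has unit
slope per GRS unit by construction.
"""

from __future__ import annotations

import importlib.resources as _resources
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "SnpPanel",
    "GenotypeDataset",
    "PanelError",
    "control_genotype_probs",
    "case_genotype_probs",
    "simulate_genotype_dataset",
    "simulate_genotype_datasets",
    "genetic_risk_score",
    "grs_quintiles",
    "default_panel",
    "DEFAULT_PANEL_RESOURCE",
]

#: shipped default panel (synthetic — see :func:`default_panel`)
DEFAULT_PANEL_RESOURCE = "snp_panel_synthetic75.tsv"

_PANEL_COLUMNS = ["snp_id", "risk_allele_freq", "odds_ratio"]


class PanelError(ValueError):
    """Raised when a SNP panel violates its constraints."""


@dataclass(frozen=True)
class SnpPanel:
    """Per-SNP risk-allele frequencies and per-allele odds ratios."""

    snp_id: tuple[str, ...]
    p: np.ndarray
    or_allele: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        orr = np.asarray(self.or_allele, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "or_allele", orr)
        if len(self.snp_id) != len(p) or len(p) != len(orr):
            raise PanelError("snp_id, p and or_allele must have equal length")
        if len(set(self.snp_id)) != len(self.snp_id):
            raise PanelError("duplicate snp_id in panel")
        if np.any((p <= 0) | (p >= 1)):
            raise PanelError("risk-allele frequencies must lie strictly in (0, 1)")
        if np.any(~np.isfinite(orr) | (orr <= 0)):
            raise PanelError("per-allele odds ratios must be finite and positive")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def log_or(self) -> np.ndarray:
        """GRS weights: natural log of the per-allele odds ratios."""
        return np.log(self.or_allele)

    @property
    def control_grs_mean(self) -> float:
        """Population GRS mean among unaffected women: sum 2 p log(OR)."""
        return float(np.sum(2.0 * self.p * self.log_or))

    @property
    def control_grs_sd(self) -> float:
        """Population GRS standard deviation: sqrt(sum 2p(1-p) log(OR)^2)."""
        return float(np.sqrt(np.sum(2.0 * self.p * (1.0 - self.p) * self.log_or**2)))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SnpPanel":
        missing = set(_PANEL_COLUMNS) - set(df.columns)
        if missing:
            raise PanelError(f"panel missing columns: {sorted(missing)}")
        return cls(
            snp_id=tuple(str(s) for s in df["snp_id"]),
            p=df["risk_allele_freq"].to_numpy(dtype=float),
            or_allele=df["odds_ratio"].to_numpy(dtype=float),
        )

    @classmethod
    def from_tsv(cls, path) -> "SnpPanel":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "risk_allele_freq": self.p,
                "odds_ratio": self.or_allele,
            }
        )

    def null(self) -> "SnpPanel":
        """Same frequencies, all odds ratios 1 (uninformative panel)."""
        return SnpPanel(self.snp_id, self.p, np.ones_like(self.or_allele))


@dataclass(frozen=True)
class GenotypeDataset:
    """One simulated replicate: risk-allele counts and their GRS."""

    replicate_index: int
    genotypes: np.ndarray  # n x m, values in {0, 1, 2}
    grs: np.ndarray  # length n


def control_genotype_probs(p: float | np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2).

    Accepts a scalar or an array of allele frequencies; the genotype axis
    is the last axis of the result.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise PanelError("allele frequency must lie strictly in (0, 1)")
    q = 1.0 - p
    return np.stack([q * q, 2.0 * p * q, p * p], axis=-1)


def case_genotype_probs(
    p: float | np.ndarray, or_allele: float | np.ndarray
) -> np.ndarray:
    """Genotype probabilities among cases: Q_g ∝ OR^g * HWE_g, normalized."""
    orr = np.asarray(or_allele, dtype=float)
    if np.any(~np.isfinite(orr) | (orr <= 0)):
        raise PanelError("odds ratio must be finite and positive")
    base = control_genotype_probs(p)
    tilt = np.stack(
        [np.ones_like(orr, dtype=float), orr, orr * orr], axis=-1
    )
    q = base * tilt
    return q / q.sum(axis=-1, keepdims=True)


def simulate_genotype_dataset(
    panel: SnpPanel,
    case_status: Sequence[int] | np.ndarray,
    replicate_index: int = 0,
    seed: int = 0,
) -> GenotypeDataset:
    """Simulate one genotype replicate conditional on case status.

    Each woman's genotype at each SNP is drawn independently from the
    control (status 0) or case (status 1) genotype distribution. The random
    substream is derived from ``(seed, replicate_index)``, so any replicate
    of a run is individually reproducible.
    """
    if len(panel) == 0:
        raise PanelError("empty SNP panel")
    status = np.asarray(case_status, dtype=int)
    if not np.isin(status, [0, 1]).all():
        raise ValueError("case_status must be binary")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), int(replicate_index))))

    ctrl = control_genotype_probs(panel.p)  # m x 3
    case = case_genotype_probs(panel.p, panel.or_allele)  # m x 3
    # cumulative thresholds for inverse-CDF sampling
    c1 = np.where(status[:, None] == 1, case[:, 0][None, :], ctrl[:, 0][None, :])
    c2 = np.where(
        status[:, None] == 1,
        (case[:, 0] + case[:, 1])[None, :],
        (ctrl[:, 0] + ctrl[:, 1])[None, :],
    )
    u = rng.random((len(status), len(panel)))
    g = (u > c1).astype(np.uint8) + (u > c2).astype(np.uint8)
    return GenotypeDataset(
        replicate_index=int(replicate_index),
        genotypes=g,
        grs=genetic_risk_score(g, panel),
    )


def simulate_genotype_datasets(
    panel: SnpPanel,
    case_status: Sequence[int] | np.ndarray,
    n_replicates: int,
    seed: int = 0,
) -> Iterator[GenotypeDataset]:
    """Yield ``n_replicates`` independent genotype replicates (lazily)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for r in range(n_replicates):
        yield simulate_genotype_dataset(panel, case_status, replicate_index=r, seed=seed)


def genetic_risk_score(genotypes: np.ndarray, panel: SnpPanel) -> np.ndarray:
    """GRS_i = sum_j log(OR_j) * g_ij."""
    g = np.asarray(genotypes)
    if g.ndim != 2 or g.shape[1] != len(panel):
        raise ValueError(
            f"genotype matrix has {g.shape[1] if g.ndim == 2 else '?'} columns, "
            f"panel has {len(panel)} SNPs"
        )
    return g.astype(float) @ panel.log_or


def grs_quintiles(grs: Sequence[float] | np.ndarray) -> np.ndarray:
    """Quintile labels 1-5 at the empirical 20/40/60/80th percentiles.

    Ties are resolved by minimum rank, so tied scores share the lowest
    quintile their rank block touches; a constant vector lands entirely in
    quintile 1.
    """
    x = np.asarray(grs, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 subjects for quintiles")
    r = rankdata(x, method="min")
    return ((r - 1) * 5 // n + 1).astype(int)


def default_panel() -> SnpPanel:
    """The shipped 75-SNP panel (synthetic).

    The panel is not a published SNP list: it is constructed once (see
    ``scripts`` in the repository) so that the number of loci is 75 and the
    population GRS moments match the screening-cohort calibration used
    throughout the package — control mean ~= 4.53 and standard deviation
    ~= 0.37, the location/scale implied by the reference quintile
    boundaries. Any user panel in the same TSV schema can be used instead.
    """
    with _resources.files("mammorisk.data").joinpath(DEFAULT_PANEL_RESOURCE).open() as fh:
        return SnpPanel.from_tsv(fh)


def build_synthetic_panel(
    n_snps: int = 75,
    grs_mean: float = 4.53,
    grs_sd: float = 0.37,
    seed: int = 20150924,
) -> SnpPanel:
    """Deterministically construct a synthetic panel with given GRS moments.

    Allele frequencies are uniform on (0.1, 0.9); log odds ratios are
    lognormal shapes rescaled by a power/scale transform solved so that the
    control-population GRS mean and standard deviation match exactly.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, size=n_snps)
    u = rng.lognormal(mean=0.0, sigma=0.5, size=n_snps)

    target_ratio = grs_mean / grs_sd

    def ratio_gap(gamma: float) -> float:
        w = u**gamma
        mean = np.sum(w * 2 * p)
        sd = np.sqrt(np.sum(w**2 * 2 * p * (1 - p)))
        return mean / sd - target_ratio

    gamma = brentq(ratio_gap, 0.01, 20.0, xtol=1e-13)
    w = u**gamma
    scale = grs_mean / np.sum(w * 2 * p)
    log_or = scale * w
    return SnpPanel(
        snp_id=tuple(f"snpSYN{i + 1:03d}" for i in range(n_snps)),
        p=p,
        or_allele=np.exp(log_or),
    )
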
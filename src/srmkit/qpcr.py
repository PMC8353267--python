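"""qPCR dCt analysis and protein-mRNA correlation.

Cycle-threshold (Ct) values are normalised against the mean of two
housekeeping genes (GAPDH and ATP5F1B by default):

    dCt = mean(Ct_hk1, Ct_hk2) - Ct_target

so that induction of a transcript (fewer cycles to threshold) raises its
plotted dCt. Replicate dCts are summarised as mean with a t-based 95% CI.
Marker profiles over the differentiation time-course are z-scaled
(mean 0, sample SD 1), compared by pairwise Pearson correlation with an
exact two-sided t test per pair, correlated against matched SRM protein
profiles, and clustered hierarchically (Euclidean distance, average
linkage) to expose co-expression groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "QpcrConfig",
    "ExpressionProfile",
    "read_ct_table",
    "compute_dct",
    "dct_table",
    "summarize_dct",
    "zscale_profile",
    "correlate_pairwise",
    "correlate_protein_mrna",
    "cluster_profiles",
]


class QpcrError(ValueError):
    """Invalid input to a qPCR analysis operation."""


@dataclass(frozen=True)
class QpcrConfig:
    housekeeping: tuple[str, str] = ("GAPDH", "ATP5F1B")
    ci_level: float = 0.95
    sig_alpha: float = 0.05
    # +1: dCt = mean(HK) - Ct_target (induction plots upward); -1 flips
    dct_sign: int = 1


@dataclass
class ExpressionProfile:
    """One marker's trajectory over ordered conditions/time points."""

    target: str
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise QpcrError("labels and values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise QpcrError(f"non-finite values in profile {self.target!r}")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct CSV with columns gene, condition, replicate, ct."""
    frame = pd.read_csv(path)
    required = ["gene", "condition", "replicate", "ct"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise QpcrError(f"Ct table missing column(s): {missing}")
    frame["ct"] = pd.to_numeric(frame["ct"], errors="coerce")
    if frame["ct"].isna().any():
        raise QpcrError("non-numeric Ct values in table")
    return frame


def compute_dct(
    ct_target: float,
    ct_hk1: float,
    ct_hk2: float,
    config: QpcrConfig | None = None,
) -> float:
    """dCt of one target against the mean of two housekeeping Cts."""
    config = config or QpcrConfig()
    for name, value in (
        ("ct_target", ct_target),
        ("ct_hk1", ct_hk1),
        ("ct_hk2", ct_hk2),
    ):
        if value is None or not np.isfinite(value):
            raise QpcrError(f"missing or non-finite {name}")
    return config.dct_sign * ((ct_hk1 + ct_hk2) / 2.0 - ct_target)


def dct_table(
    ct: pd.DataFrame, config: QpcrConfig | None = None
) -> pd.DataFrame:
    """Per-replicate dCt for every non-housekeeping gene.

    Housekeeping Cts are matched within (condition, replicate); a
    missing housekeeping measurement is an error.
    """
    config = config or QpcrConfig()
    hk1, hk2 = config.housekeeping
    hk = ct[ct["gene"].isin([hk1, hk2])]
    targets = ct[~ct["gene"].isin([hk1, hk2])]
    hk_map = hk.set_index(["gene", "condition", "replicate"])["ct"]
    rows = []
    for row in targets.itertuples():
        try:
            c1 = float(hk_map.loc[(hk1, row.condition, row.replicate)])
            c2 = float(hk_map.loc[(hk2, row.condition, row.replicate)])
        except KeyError as exc:
            raise QpcrError(
                f"missing housekeeping Ct for condition {row.condition!r} "
                f"replicate {row.replicate!r}"
            ) from exc
        rows.append(
            {
                "gene": row.gene,
                "condition": row.condition,
                "replicate": row.replicate,
                "dct": compute_dct(row.ct, c1, c2, config),
            }
        )
    return pd.DataFrame(rows)


def summarize_dct(
    dcts: Iterable[float], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Mean dCt with a t-based confidence interval over replicates."""
    v = np.asarray(list(dcts), dtype=float)
    if v.size == 0:
        raise QpcrError("no replicate dCt values")
    mean = float(np.mean(v))
    if v.size < 2:
        return mean, float("nan"), float("nan")
    se = float(np.std(v, ddof=1) / np.sqrt(v.size))
    tq = float(stats.t.ppf(0.5 + ci_level / 2.0, v.size - 1))
    return mean, mean - tq * se, mean + tq * se


def zscale_profile(values: Sequence[float]) -> np.ndarray:
    """Centre to mean 0 and scale to sample SD 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise QpcrError("need >= 2 values to z-scale")
    sd = float(np.std(v, ddof=1))
    if sd == 0:
        raise QpcrError("cannot z-scale a constant series")
    return (v - np.mean(v)) / sd


def _check_shared_labels(profiles: Sequence[ExpressionProfile]) -> None:
    labels = profiles[0].labels
    for p in profiles[1:]:
        if p.labels != labels:
            raise QpcrError(
                f"profiles {profiles[0].target!r} and {p.target!r} have "
                "mismatched time labels"
            )


def correlate_pairwise(
    profiles: Sequence[ExpressionProfile],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over the time-course.

    Returns (r matrix, p matrix, significance flags); each pair's p is
    the exact two-sided t test, uncorrected for the number of cells.
    """
    if len(profiles) < 2:
        raise QpcrError("need >= 2 profiles")
    _check_shared_labels(profiles)
    n = profiles[0].values.size
    if n < 3:
        raise QpcrError("need >= 3 shared time points")
    targets = [p.target for p in profiles]
    k = len(profiles)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(profiles[i].values, profiles[j].values)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rf = pd.DataFrame(r, index=targets, columns=targets)
    pf = pd.DataFrame(p, index=targets, columns=targets)
    sig = (pf < alpha) & ~np.eye(k, dtype=bool)
    return rf, pf, sig


def correlate_protein_mrna(
    protein: ExpressionProfile, mrna: ExpressionProfile
) -> tuple[float, float]:
    """Pearson correlation of z-scaled protein and transcript profiles."""
    _check_shared_labels([protein, mrna])
    if protein.values.size < 3:
        raise QpcrError("need >= 3 shared time points")
    res = stats.pearsonr(
        zscale_profile(protein.values), zscale_profile(mrna.values)
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClusterResult:
    leaf_order: list[str]
    linkage: np.ndarray
    targets: list[str] = field(default_factory=list)


def cluster_profiles(profiles: Sequence[ExpressionProfile]) -> ClusterResult:
    """Agglomerative clustering of profiles (Euclidean, average linkage).

    Profiles are sorted by target id before linkage so the tree topology
    does not depend on input order; remaining ties are broken by scipy's
    deterministic index order.
    """
    if len(profiles) < 2:
        raise QpcrError("need >= 2 profiles to cluster")
    _check_shared_labels(profiles)
    ordered = sorted(profiles, key=lambda p: p.target)
    matrix = np.vstack([p.values for p in ordered])
    link = hierarchy.linkage(pdist(matrix), method="average")
    leaves = hierarchy.leaves_list(link)
    targets = [p.target for p in ordered]
    return ClusterResult(
        leaf_order=[targets[i] for i in leaves],
        linkage=link,
        targets=targets,
    )
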
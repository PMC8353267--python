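"""SRM transition-level quantification.

Implements the quantification rules of the assay: light/heavy co-elution
verification (retention-time match plus normalised fragment-intensity dot
product), per-peak-group signal-to-noise filtering (the top transition of
a peptide's peak group must exceed S/N 3), one-third-of-background
imputation for transitions below their transition-specific background,
log2 median-of-transition peptide abundances, detectable/quantifiable
protein calls, mixed-effects condition-versus-control log2 fold-changes
with Benjamini-Hochberg FDR control, and per-condition median/CI
summaries.

Quantification consumes light-label peak areas; heavy areas serve
co-elution verification (an optional ratio-to-heavy mode normalises each
light area by its heavy twin before log2 transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "REPORT_COLUMNS",
    "QuantConfig",
    "DetectionCall",
    "ComparisonResult",
    "CoelutionResult",
    "read_transition_report",
    "verify_coelution",
    "coelution_report",
    "filter_peak_groups",
    "impute_below_background",
    "peptide_abundance",
    "peptide_abundances",
    "protein_abundances",
    "call_detection",
    "detection_calls",
    "fit_group_comparison",
    "compare_all",
    "adjust_bh",
    "summarize_condition",
    "condition_summaries",
]

REPORT_COLUMNS = [
    "protein",
    "peptide_sequence",
    "precursor_charge",
    "fragment",
    "fragment_charge",
    "label",
    "condition",
    "replicate",
    "run_id",
    "rt_observed",
    "peak_area",
    "background",
    "snr",
]

_GROUP_KEY = [
    "protein",
    "peptide_sequence",
    "precursor_charge",
    "condition",
    "replicate",
    "run_id",
]


class QuantError(ValueError):
    """Invalid input to a quantification operation."""


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds of the quantification pipeline.

    ``snr_threshold`` is strict (S/N must exceed 3); an area strictly
    below its background is replaced by ``imputation_factor`` times the
    background. ``ratio_to_heavy`` switches quantification from light
    areas to light/heavy ratios (off by default).
    """

    snr_threshold: float = 3.0
    imputation_factor: float = 1.0 / 3.0
    min_peptides_quantifiable: int = 2
    min_replicates_detected: int = 3
    fdr_alpha: float = 0.05
    ci_level: float = 0.95
    control_condition: str = "NSC"
    coelution_dotp_min: float = 0.9
    coelution_rt_tol: float = 0.5  # min
    ratio_to_heavy: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.imputation_factor < 1:
            raise QuantError("imputation_factor must be in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise QuantError("fdr_alpha must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise QuantError("ci_level must be in (0, 1)")


# ---------------------------------------------------------------------------
# Input


def read_transition_report(
    path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a Skyline-export-like transition report CSV.

    Returns ``(records, rejected)``: rejected rows (negative or
    non-finite peak_area/background/snr, unknown label) carry their
    1-based CSV line number and a reason; every input row lands in
    exactly one of the two frames.
    """
    frame = pd.read_csv(path)
    missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
    if missing:
        raise QuantError(f"transition report missing column(s): {missing}")
    frame = frame[REPORT_COLUMNS].copy()
    frame["line"] = np.arange(2, len(frame) + 2)  # 1-based, after header
    for col in ("peak_area", "background", "snr", "rt_observed"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    bad_value = (
        ~np.isfinite(frame["peak_area"])
        | ~np.isfinite(frame["background"])
        | ~np.isfinite(frame["snr"])
        | (frame["peak_area"] < 0)
        | (frame["background"] < 0)
        | (frame["snr"] < 0)
    )
    bad_label = ~frame["label"].isin(["light", "heavy"])
    bad = bad_value | bad_label
    rejected = frame[bad].copy()
    rejected["reason"] = np.where(
        bad_label[bad], "unknown label", "negative or non-finite value"
    )
    records = frame[~bad].drop(columns=["line"]).reset_index(drop=True)
    return records, rejected.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Co-elution verification


@dataclass(frozen=True)
class CoelutionResult:
    passed: bool
    delta_rt: float  # |mean RT(light) - mean RT(heavy)|, min
    dotp: float  # normalised fragment-area dot product
    n_fragments: int


def verify_coelution(
    light: pd.DataFrame,
    heavy: pd.DataFrame,
    config: QuantConfig | None = None,
) -> CoelutionResult:
    """Check that a light peak group co-elutes with its heavy twin.

    Fragments are matched on (fragment, fragment_charge); the normalised
    dot product of the two fragment-area vectors is scale-invariant, so
    a constant spike-in level does not affect the check.
    """
    config = config or QuantConfig()
    key = ["fragment", "fragment_charge"]
    lv = light.groupby(key)["peak_area"].mean()
    hv = heavy.groupby(key)["peak_area"].mean()
    shared = lv.index.intersection(hv.index)
    if len(shared) == 0:
        raise QuantError("no shared fragments between light and heavy groups")
    a = lv.loc[shared].to_numpy(dtype=float)
    b = hv.loc[shared].to_numpy(dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    dotp = float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0
    delta_rt = float(
        abs(light["rt_observed"].mean() - heavy["rt_observed"].mean())
    )
    passed = (
        delta_rt <= config.coelution_rt_tol and dotp >= config.coelution_dotp_min
    )
    return CoelutionResult(
        passed=passed, delta_rt=delta_rt, dotp=dotp, n_fragments=len(shared)
    )


def coelution_report(
    report: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Co-elution diagnostics for every peak group with a heavy twin."""
    config = config or QuantConfig()
    rows = []
    for key, grp in report.groupby(_GROUP_KEY, sort=False):
        light = grp[grp["label"] == "light"]
        heavy = grp[grp["label"] == "heavy"]
        if light.empty or heavy.empty:
            continue
        res = verify_coelution(light, heavy, config)
        rows.append(
            dict(zip(_GROUP_KEY, key))
            | {
                "delta_rt": res.delta_rt,
                "dotp": res.dotp,
                "n_fragments": res.n_fragments,
                "passed": res.passed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Filtering and imputation


def filter_peak_groups(
    report: pd.DataFrame, config: QuantConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the top-transition S/N rule per peak group.

    A peptide's peak group in a run (light and heavy rows together) is
    retained iff the top transition — the light transition with the
    highest peak area in that run — has S/N strictly above the
    threshold. Returns ``(retained, rejected)``; every input row appears
    in exactly one.
    """
    config = config or QuantConfig()
    if report.empty:
        empty = report.copy()
        rej = report.copy()
        rej["reason"] = pd.Series(dtype=str)
        return empty, rej
    keep_masks = []
    reasons = []
    for _, grp in report.groupby(_GROUP_KEY, sort=False):
        light = grp[grp["label"] == "light"]
        if light.empty:
            keep_masks.append((grp.index, False))
            reasons.append("no light transitions in peak group")
            continue
        top = light.loc[light["peak_area"].idxmax()]
        ok = top["snr"] > config.snr_threshold
        keep_masks.append((grp.index, bool(ok)))
        reasons.append(
            ""
            if ok
            else f"top transition S/N {top['snr']:.3g} <= {config.snr_threshold:g}"
        )
    keep = pd.Series(False, index=report.index)
    reason = pd.Series("", index=report.index)
    for (idx, ok), why in zip(keep_masks, reasons):
        keep.loc[idx] = ok
        if not ok:
            reason.loc[idx] = why
    retained = report[keep].copy()
    rejected = report[~keep].copy()
    rejected["reason"] = reason[~keep]
    return retained, rejected


def impute_below_background(peak_area, background, factor: float = 1.0 / 3.0):
    """Replace areas strictly below their background by factor*background.

    Accepts scalars or arrays; idempotent as long as
    ``factor * background >= background`` is never true (factor < 1).
    """
    area = np.asarray(peak_area, dtype=float)
    bg = np.asarray(background, dtype=float)
    if np.any(area < 0) or np.any(bg < 0):
        raise QuantError("peak_area and background must be non-negative")
    out = np.where(area < bg, factor * bg, area)
    if np.isscalar(peak_area) or np.ndim(peak_area) == 0:
        return float(out)
    return out


def peptide_abundance(log2_areas: Iterable[float]) -> float:
    """Peptide abundance in one run: median of transition log2 areas."""
    values = np.asarray(list(log2_areas), dtype=float)
    if values.size == 0:
        raise QuantError("no transition values for peptide abundance")
    return float(np.median(values))


def _quant_values(retained: pd.DataFrame, config: QuantConfig) -> pd.DataFrame:
    """Per-transition log2 quantification values from retained rows.

    Default: log2 of the imputed light area. Ratio mode: log2 of the
    imputed light area minus log2 of the matched heavy area.
    """
    light = retained[retained["label"] == "light"].copy()
    if light.empty:
        raise QuantError("no light-label rows to quantify")
    light["log2_area"] = np.log2(
        np.maximum(
            impute_below_background(
                light["peak_area"].to_numpy(),
                light["background"].to_numpy(),
                config.imputation_factor,
            ),
            np.finfo(float).tiny,
        )
    )
    if config.ratio_to_heavy:
        heavy = retained[retained["label"] == "heavy"]
        key = _GROUP_KEY + ["fragment", "fragment_charge"]
        hmap = heavy.set_index(key)["peak_area"]
        idx = pd.MultiIndex.from_frame(light[key])
        harea = hmap.reindex(idx).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            light["log2_area"] = light["log2_area"].to_numpy() - np.log2(harea)
        light = light[np.isfinite(light["log2_area"])]
    return light


def peptide_abundances(
    retained: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Median-of-transition log2 abundances per peptide per run."""
    config = config or QuantConfig()
    light = _quant_values(retained, config)
    out = (
        light.groupby(
            ["protein", "peptide_sequence", "condition", "replicate", "run_id"],
            sort=False,
        )["log2_area"]
        .median()
        .reset_index()
        .rename(columns={"log2_area": "abundance"})
    )
    return out


def protein_abundances(
    retained: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Protein abundance per run: median over its peptide abundances."""
    peps = peptide_abundances(retained, config)
    return (
        peps.groupby(["protein", "condition", "replicate", "run_id"], sort=False)[
            "abundance"
        ]
        .median()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Detection calls


@dataclass(frozen=True)
class DetectionCall:
    """Quantifiable/detectable/not_detected status of a protein."""

    protein_id: str
    condition: str
    status: str
    n_peptides_detected: int
    replicate_counts: Mapping[str, int]


def call_detection(
    peptide_replicates: Mapping[str, Iterable],
    protein_id: str = "",
    condition: str = "",
    config: QuantConfig | None = None,
) -> DetectionCall:
    """Classify a protein in one condition from its detection matrix.

    ``peptide_replicates`` maps peptide sequence -> replicates in which
    its peak group survived filtering. Quantifiable: >= 2 distinct
    peptides each detected in >= 3 replicates. Detectable: at least one
    peptide detected somewhere but the quantifiable rule unmet.
    """
    config = config or QuantConfig()
    counts = {pep: len(set(reps)) for pep, reps in peptide_replicates.items()}
    counts = {pep: n for pep, n in counts.items() if n > 0}
    n_solid = sum(
        1 for n in counts.values() if n >= config.min_replicates_detected
    )
    if n_solid >= config.min_peptides_quantifiable:
        status = "quantifiable"
    elif counts:
        status = "detectable"
    else:
        status = "not_detected"
    return DetectionCall(
        protein_id=protein_id,
        condition=condition,
        status=status,
        n_peptides_detected=len(counts),
        replicate_counts=counts,
    )


def detection_calls(
    retained: pd.DataFrame,
    config: QuantConfig | None = None,
    universe: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Detection calls for every protein x condition.

    ``universe`` (e.g. the unfiltered report) widens the set of
    protein x condition pairs so proteins whose every peak group was
    filtered out are reported as not_detected rather than omitted.
    """
    config = config or QuantConfig()
    light = retained[retained["label"] == "light"]
    pairs = list(
        light.groupby(["protein", "condition"], sort=False).groups
    )
    if universe is not None:
        seen = set(pairs)
        for key in universe.groupby(["protein", "condition"], sort=False).groups:
            if key not in seen:
                pairs.append(key)
                seen.add(key)
    rows = []
    for protein, condition in pairs:
        grp = light[
            (light["protein"] == protein) & (light["condition"] == condition)
        ]
        pep_reps = {
            pep: set(sub["replicate"])
            for pep, sub in grp.groupby("peptide_sequence", sort=False)
        }
        call = call_detection(pep_reps, protein, condition, config)
        rows.append(
            {
                "protein": protein,
                "condition": condition,
                "status": call.status,
                "n_peptides_detected": call.n_peptides_detected,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein", "condition", "status", "n_peptides_detected"]
    )


# ---------------------------------------------------------------------------
# Mixed-effects group comparison


@dataclass(frozen=True)
class ComparisonResult:
    protein_id: str
    condition: str
    control: str
    log2fc: float
    se: float
    t_value: float
    df: float
    p_value: float
    adj_p_value: float = float("nan")
    significant: bool = False
    model: str = "mixed"  # "mixed" | "fixed"


def fit_group_comparison(
    retained: pd.DataFrame,
    condition: str,
    control: str,
    config: QuantConfig | None = None,
    protein_id: str | None = None,
) -> ComparisonResult:
    """Condition-versus-control log2 fold-change for one protein.

    Fits y_fr = mu + C_case + F_f + R_r + eps on transition-level log2
    abundances (feature = peptide/charge/fragment fixed effect, run
    random intercept). With a single feature, or when the run-variance
    estimate collapses to zero, the model degrades to the fixed-effects
    two-way layout. The contrast df is the between-run df (n_runs - 2)
    for the mixed fit and the residual df for the fixed fallback.
    """
    config = config or QuantConfig()
    data = retained[retained["condition"].isin([condition, control])]
    if protein_id is not None:
        data = data[data["protein"] == protein_id]
    else:
        ids = data["protein"].unique()
        if len(ids) != 1:
            raise QuantError(
                "fit_group_comparison needs a single protein; pass protein_id"
            )
        protein_id = ids[0]
    light = _quant_values(data, config)
    light = light.copy()
    light["feature"] = (
        light["peptide_sequence"]
        + "/"
        + light["precursor_charge"].astype(str)
        + "/"
        + light["fragment"]
        + "/"
        + light["fragment_charge"].astype(str)
    )
    light["case"] = (light["condition"] == condition).astype(float)
    n_runs = light["run_id"].nunique()
    runs_per_group = light.groupby("case")["run_id"].nunique()
    if n_runs <= 1:
        raise QuantError("singular design: only one run in total")
    if len(runs_per_group) < 2 or runs_per_group.min() < 2:
        raise QuantError(
            f"need >= 2 runs per group for {protein_id} "
            f"({condition} vs {control})"
        )
    n_features = light["feature"].nunique()
    formula = "log2_area ~ case" + (
        " + C(feature)" if n_features > 1 else ""
    )

    model_kind = "mixed"
    result = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, light, groups=light["run_id"])
            fit = md.fit(reml=True)
        # degrade when the run variance collapses to zero or the residual
        # variance vanishes (ill-conditioned GLS weighting)
        if (
            np.isfinite(fit.params["case"])
            and float(fit.cov_re.iloc[0, 0]) > 1e-8
            and float(fit.scale) > 1e-10
        ):
            result = fit
    except (np.linalg.LinAlgError, ValueError):
        result = None
    if result is not None:
        est = float(result.params["case"])
        se = float(result.bse["case"])
        dof = float(n_runs - 2)
    else:
        model_kind = "fixed"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols(formula, light).fit()
        est = float(ols.params["case"])
        se = float(ols.bse["case"])
        dof = float(ols.df_resid)
    if se == 0 or not np.isfinite(se):
        t_value = np.inf if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        t_value = est / se
        p = float(2.0 * stats.t.sf(abs(t_value), dof))
    return ComparisonResult(
        protein_id=protein_id,
        condition=condition,
        control=control,
        log2fc=est,
        se=se,
        t_value=float(t_value),
        df=dof,
        p_value=p,
        model=model_kind,
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise QuantError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_all(
    retained: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """All condition-vs-control comparisons with per-condition BH-FDR.

    A protein enters a comparison when it is quantifiable in the
    condition or in the control; BH is applied across proteins within
    each condition-vs-control comparison.
    """
    config = config or QuantConfig()
    control = config.control_condition
    calls = detection_calls(retained, config)
    status = {
        (r.protein, r.condition): r.status for r in calls.itertuples()
    }
    conditions = [
        c for c in retained["condition"].unique() if c != control
    ]
    rows = []
    for condition in conditions:
        fits: list[ComparisonResult] = []
        for protein in sorted(retained["protein"].unique()):
            quantifiable = (
                status.get((protein, condition)) == "quantifiable"
                or status.get((protein, control)) == "quantifiable"
            )
            if not quantifiable:
                continue
            try:
                fits.append(
                    fit_group_comparison(
                        retained, condition, control, config, protein_id=protein
                    )
                )
            except QuantError:
                continue
        if not fits:
            continue
        adj = adjust_bh([f.p_value for f in fits])
        for f, a in zip(fits, adj):
            rows.append(
                {
                    "protein": f.protein_id,
                    "condition": condition,
                    "control": control,
                    "status": "quantifiable",
                    "log2fc": f.log2fc,
                    "se": f.se,
                    "t_value": f.t_value,
                    "df": f.df,
                    "p_value": f.p_value,
                    "adj_p_value": float(a),
                    "significant": bool(a <= config.fdr_alpha),
                    "model": f.model,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein",
            "condition",
            "control",
            "status",
            "log2fc",
            "se",
            "t_value",
            "df",
            "p_value",
            "adj_p_value",
            "significant",
            "model",
        ],
    )


# ---------------------------------------------------------------------------
# Condition summaries


def summarize_condition(
    values: Iterable[float], ci_level: float = 0.95
) -> tuple[float, float, float]:
    """Median and t-interval of replicate-level protein abundances.

    The CI is the t-interval about the mean (displayed alongside the
    median); with a single replicate only the median is defined.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise QuantError("no replicate values to summarise")
    med = float(np.median(v))
    if v.size < 2:
        return med, float("nan"), float("nan")
    mean = float(np.mean(v))
    se = float(np.std(v, ddof=1) / np.sqrt(v.size))
    tq = float(stats.t.ppf(0.5 + ci_level / 2.0, v.size - 1))
    return med, mean - tq * se, mean + tq * se


def condition_summaries(
    retained: pd.DataFrame, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Per protein x condition: median abundance and CI over replicates."""
    config = config or QuantConfig()
    prot = protein_abundances(retained, config)
    rows = []
    for (protein, condition), grp in prot.groupby(
        ["protein", "condition"], sort=False
    ):
        med, lo, hi = summarize_condition(grp["abundance"], config.ci_level)
        rows.append(
            {
                "protein": protein,
                "condition": condition,
                "n_replicates": len(grp),
                "median": med,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)
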
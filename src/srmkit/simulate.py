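"""Ground-truth-annotated synthetic SRM time-courses.

Emulates a neural-differentiation SRM experiment at the transition-report
level so every pipeline stage can be exercised against known truth. The
generative model mirrors the structure the quantification model fits:

    log2 area[p,q,f,r] = T_p(time_r) + beta_q + log2 phi_f + u_r + eps

with per-protein piecewise-linear log2 trajectories T_p over the
differentiation time-course (neuronal markers rising, NSC markers
falling, S100B dipping then rising), peptide digestion-efficiency offsets
beta_q ~ N(0, 0.5^2), fixed per-peptide fragment-intensity fractions
phi_f (Dirichlet-drawn, summing to 1), run random effects
u_r ~ N(0, 0.1^2), and Gaussian measurement noise eps ~ N(0, 0.2^2).
Areas are reported on the linear scale with transition-specific
backgrounds; areas that fall below background are reported as-is (with
their background) so the pipeline's one-third-background imputation is
exercised. Heavy spike-ins sit at a constant log2 level with the same
fragment profile. S/N is reported as area/background — a declared proxy
for the peak-picker's estimate. A matched qPCR Ct table couples each
marker's transcript to its protein trajectory with a negative slope
(higher protein => fewer cycles => higher dCt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .defaults import default_panel
from .design import ProteinPanel
from .quant import REPORT_COLUMNS

__all__ = [
    "DEFAULT_CONDITIONS",
    "DEFAULT_TRAJECTORIES",
    "SimulationConfig",
    "GroundTruth",
    "generate_timecourse",
    "inject_dropout",
    "simulate_group_comparison",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# condition label -> time (days of differentiation)
DEFAULT_CONDITIONS: tuple[tuple[str, float], ...] = (
    ("NSC", 0.0),
    ("BG7", 7.0),
    ("BG14", 14.0),
    ("BG21", 21.0),
    ("BG28", 28.0),
)

# mean log2 abundance at the default time points (0, 7, 14, 21, 28 d);
# qualitative shapes: neuronal rising, NSC falling, S100B dip-then-rise,
# OCT4 below background (exercises censoring), GFAP/OLIG1 near the
# detection limit, GALC dropping then steady.
DEFAULT_TRAJECTORIES: dict[str, tuple[float, ...]] = {
    "OCT4": (8.0, 7.5, 7.2, 7.0, 7.0),
    "SOX2": (15.0, 15.0, 14.3, 13.6, 13.0),
    "NES": (15.5, 14.8, 14.2, 13.8, 13.5),
    "DCX": (12.5, 14.0, 15.0, 15.7, 15.5),
    "TUBB3": (14.5, 14.6, 15.2, 15.8, 16.2),
    "MAP2": (13.5, 14.2, 14.9, 15.4, 15.8),
    "GFAP": (10.6, 10.3, 10.2, 10.3, 10.4),
    "S100B": (14.5, 13.2, 13.6, 14.3, 15.0),
    "GALC": (11.2, 10.6, 10.6, 10.7, 10.6),
    "OLIG1": (10.9, 10.4, 10.3, 10.4, 10.3),
}

_FLAT_BASELINE = 14.0  # log2, proteins without a named trajectory


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic time-course."""

    panel: ProteinPanel | None = None
    conditions: tuple[tuple[str, float], ...] = DEFAULT_CONDITIONS
    replicates: int = 4
    trajectories: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAJECTORIES)
    )
    peptide_offset_sd: float = 0.5  # log2, digestion-efficiency spread
    fragment_profiles: Mapping[str, Sequence[float]] | None = None
    sigma_run: float = 0.1  # log2, run random effect
    sigma_noise: float = 0.2  # log2, transition measurement noise
    background_log2_mean: float = 8.0
    background_log2_sd: float = 0.7
    heavy_level: float = 16.0  # log2, constant spike-in per peptide
    lod_censoring: bool = True
    rt_slope: float = 0.3  # min per iRT unit, true calibration
    rt_intercept: float = 5.0  # min
    rt_jitter_sd: float = 0.05  # min
    ct_replicates: int = 3
    ct_intercept: float = 38.0  # cycles at zero log2 abundance
    ct_slope: float = 1.0  # cycles per log2 unit (negative coupling)
    ct_sd: float = 0.25  # cycles
    housekeeping_ct: Mapping[str, float] = field(
        default_factory=lambda: {"GAPDH": 17.5, "ATP5F1B": 19.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise SimulationError("replicates must be >= 2")
        for name in (
            "peptide_offset_sd",
            "sigma_run",
            "sigma_noise",
            "background_log2_sd",
            "rt_jitter_sd",
            "ct_sd",
        ):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if len(self.conditions) < 2:
            raise SimulationError("need >= 2 conditions")
        for key, values in self.trajectories.items():
            if len(values) != len(self.conditions):
                raise SimulationError(
                    f"trajectory for {key!r} has {len(values)} values, "
                    f"expected {len(self.conditions)}"
                )
        if self.fragment_profiles is not None:
            for pep, fracs in self.fragment_profiles.items():
                if abs(sum(fracs) - 1.0) > 1e-9:
                    raise SimulationError(
                        f"fragment profile for {pep!r} does not sum to 1"
                    )


@dataclass
class GroundTruth:
    """Realised simulation truth, keyed like the generated report."""

    protein_conditions: pd.DataFrame  # protein, condition, true log2, true fc
    run_effects: pd.DataFrame  # run_id, effect

    def true_log2fc(self, protein: str, condition: str) -> float:
        sub = self.protein_conditions
        row = sub[
            (sub["protein"] == protein) & (sub["condition"] == condition)
        ]
        if row.empty:
            raise KeyError((protein, condition))
        return float(row["true_log2fc"].iloc[0])


def _trajectory(config: SimulationConfig, protein: str) -> np.ndarray:
    values = config.trajectories.get(protein)
    if values is None:
        values = [_FLAT_BASELINE] * len(config.conditions)
    return np.asarray(values, dtype=float)


def generate_timecourse(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (transition report, Ct table, ground truth).

    Deterministic: the same config (including seed) yields byte-identical
    frames. The first condition is the control; true log2 fold-changes
    are reported against it.
    """
    config = config or SimulationConfig()
    panel = config.panel or default_panel()
    rng = np.random.default_rng(config.seed)
    conditions = list(config.conditions)

    # run effects shared by all proteins measured in that run
    run_ids = [
        (cond, rep, f"{cond}_r{rep}")
        for cond, _ in conditions
        for rep in range(1, config.replicates + 1)
    ]
    run_effect = {
        run: rng.normal(0.0, config.sigma_run) for _, _, run in run_ids
    }

    report_rows: list[dict] = []
    truth_rows: list[dict] = []
    for prot in panel.proteins:
        traj = _trajectory(config, prot.protein_id)
        for (cond, _t), level in zip(conditions, traj):
            truth_rows.append(
                {
                    "protein": prot.protein_id,
                    "condition": cond,
                    "true_log2_abundance": float(level),
                    "true_log2fc": float(level - traj[0]),
                }
            )
        for pep in prot.peptides:
            beta = rng.normal(0.0, config.peptide_offset_sd)
            coords = sorted(
                {t.coordinates() for t in pep.transitions},
                key=lambda c: (c[1], c[2], -c[3], c[4]),
            )
            if (
                config.fragment_profiles is not None
                and pep.spec.sequence in config.fragment_profiles
            ):
                phi = np.asarray(
                    config.fragment_profiles[pep.spec.sequence], dtype=float
                )
                if phi.size != len(coords):
                    raise SimulationError(
                        f"fragment profile for {pep.spec.sequence!r} has "
                        f"{phi.size} entries, expected {len(coords)}"
                    )
            else:
                phi = rng.dirichlet(np.full(len(coords), 2.0))
            backgrounds = 2.0 ** rng.normal(
                config.background_log2_mean,
                config.background_log2_sd,
                size=len(coords),
            )
            rt_centre = (
                config.rt_slope * (pep.spec.irt if pep.spec.irt is not None else 50.0)
                + config.rt_intercept
            )
            for (cond, _t), level in zip(conditions, traj):
                for rep in range(1, config.replicates + 1):
                    run = f"{cond}_r{rep}"
                    u = run_effect[run]
                    rt = rt_centre + rng.normal(0.0, config.rt_jitter_sd)
                    for coord, frac, bg in zip(coords, phi, backgrounds):
                        _seq, zc, series, idx, fz = coord
                        log2_light = (
                            level
                            + beta
                            + np.log2(frac)
                            + u
                            + rng.normal(0.0, config.sigma_noise)
                        )
                        area = float(2.0**log2_light)
                        if not config.lod_censoring:
                            area = max(area, float(bg))
                        log2_heavy = (
                            config.heavy_level
                            + np.log2(frac)
                            + u
                            + rng.normal(0.0, config.sigma_noise)
                        )
                        heavy_area = float(2.0**log2_heavy)
                        for label, a in (("light", area), ("heavy", heavy_area)):
                            report_rows.append(
                                {
                                    "protein": prot.protein_id,
                                    "peptide_sequence": pep.spec.sequence,
                                    "precursor_charge": zc,
                                    "fragment": f"{series}{idx}",
                                    "fragment_charge": fz,
                                    "label": label,
                                    "condition": cond,
                                    "replicate": rep,
                                    "run_id": run,
                                    "rt_observed": round(float(rt), 4),
                                    "peak_area": round(a, 4),
                                    "background": round(float(bg), 4),
                                    "snr": round(a / float(bg), 4),
                                }
                            )
    report = pd.DataFrame(report_rows, columns=REPORT_COLUMNS)

    # matched qPCR Ct table
    ct_rows: list[dict] = []
    marker_ids = [p.protein_id for p in panel.proteins]
    for gene in marker_ids:
        traj = _trajectory(config, gene)
        for (cond, _t), level in zip(conditions, traj):
            for rep in range(1, config.ct_replicates + 1):
                ct = (
                    config.ct_intercept
                    - config.ct_slope * level
                    + rng.normal(0.0, config.ct_sd)
                )
                ct_rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": round(float(ct), 4),
                    }
                )
    for gene, base in config.housekeeping_ct.items():
        for cond, _t in conditions:
            for rep in range(1, config.ct_replicates + 1):
                ct_rows.append(
                    {
                        "gene": gene,
                        "condition": cond,
                        "replicate": rep,
                        "ct": round(float(base + rng.normal(0.0, config.ct_sd)), 4),
                    }
                )
    ct_table = pd.DataFrame(ct_rows, columns=["gene", "condition", "replicate", "ct"])

    truth = GroundTruth(
        protein_conditions=pd.DataFrame(truth_rows),
        run_effects=pd.DataFrame(
            [{"run_id": run, "effect": eff} for (_, _, run), eff in zip(run_ids, run_effect.values())]
        ),
    )
    return report, ct_table, truth


def inject_dropout(
    report: pd.DataFrame,
    protein: str,
    condition: str,
    keep_peptides: int,
) -> pd.DataFrame:
    """Remove all but ``keep_peptides`` peptides of a protein/condition.

    Builds fixtures for detection-call behaviour (a protein left with one
    peptide becomes detectable, with none not_detected). Peptides are
    kept in sorted-sequence order for determinism.
    """
    mask = (report["protein"] == protein) & (report["condition"] == condition)
    if not mask.any():
        raise SimulationError(
            f"protein {protein!r} not present in condition {condition!r}"
        )
    peptides = sorted(report.loc[mask, "peptide_sequence"].unique())
    if keep_peptides > len(peptides):
        raise SimulationError(
            f"keep_peptides={keep_peptides} exceeds the {len(peptides)} "
            "peptides available"
        )
    kept = set(peptides[:keep_peptides])
    drop = mask & ~report["peptide_sequence"].isin(kept)
    return report[~drop].reset_index(drop=True)


def simulate_group_comparison(
    rng: np.random.Generator,
    true_log2fc: float,
    n_peptides: int = 2,
    n_transitions: int = 3,
    n_replicates: int = 4,
    sigma_run: float = 0.1,
    sigma_noise: float = 0.2,
    peptide_offset_sd: float = 0.5,
    baseline: float = 14.0,
    condition: str = "BG28",
    control: str = "NSC",
    protein: str = "SIM",
) -> pd.DataFrame:
    """One protein's two-group transition report with known log2fc.

    Minimal single-comparison counterpart of :func:`generate_timecourse`
    (same error structure, no censoring: backgrounds are negligible and
    S/N is large) for parameter-recovery and null-calibration studies.
    """
    # peptide offsets and fragment profiles are fixed effects: draw once
    betas = {q: rng.normal(0.0, peptide_offset_sd) for q in range(n_peptides)}
    phis = {
        q: rng.dirichlet(np.full(n_transitions, 2.0)) for q in range(n_peptides)
    }
    report_rows = []
    for cond, level in ((control, baseline), (condition, baseline + true_log2fc)):
        for rep in range(1, n_replicates + 1):
            run = f"{cond}_r{rep}"
            u = rng.normal(0.0, sigma_run)
            for q in range(n_peptides):
                pep = f"PEPTIDE{q}K"
                for f in range(n_transitions):
                    log2_area = (
                        level
                        + betas[q]
                        + np.log2(phis[q][f])
                        + u
                        + rng.normal(0.0, sigma_noise)
                    )
                    area = float(2.0**log2_area)
                    report_rows.append(
                        {
                            "protein": protein,
                            "peptide_sequence": pep,
                            "precursor_charge": 2,
                            "fragment": f"y{f + 3}",
                            "fragment_charge": 1,
                            "label": "light",
                            "condition": cond,
                            "replicate": rep,
                            "run_id": run,
                            "rt_observed": 15.0,
                            "peak_area": area,
                            "background": 1.0,
                            "snr": area,
                        }
                    )
    return pd.DataFrame(report_rows, columns=REPORT_COLUMNS)
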
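"""Synthetic default 10-marker panel.

The shipped panel targets the ten neural-differentiation markers the assay
was built around (OCT4, SOX2, NES, DCX, TUBB3, MAP2, GFAP, S100B, GALC,
OLIG1), but the protein sequences here are SYNTHETIC: deterministic,
seed-generated stand-ins assembled from designed tryptic peptides. They
give every marker >= 4 proteotypic candidate peptides of SRM-friendly
length, so the full design -> schedule -> simulate -> quantify pipeline can
run without any external sequence database. m/z coordinates therefore do
not correspond to the human proteins.

A NANOG-like decoy pair is included: every NANOG tryptic peptide also
occurs in a second proteome entry, so panel construction excludes it for
lack of proteotypic peptides — the behaviour seen for real NANOG against
the human proteome.
"""

from __future__ import annotations

import numpy as np

from .design import DesignConfig, ProteinPanel, build_panel, digest_protein

__all__ = [
    "MARKERS",
    "default_targets",
    "default_proteome",
    "default_irt",
    "default_panel",
]

# marker -> lineage class (used by the simulator's default trajectories)
MARKERS = {
    "OCT4": "esc",
    "SOX2": "nsc",
    "NES": "nsc",
    "DCX": "neuronal",
    "TUBB3": "neuronal",
    "MAP2": "neuronal",
    "GFAP": "astrocyte",
    "S100B": "astrocyte",
    "GALC": "oligodendrocyte",
    "OLIG1": "oligodendrocyte",
}

_SEED = 20210806  # fixed: the synthetic proteome is part of the package
_RESIDUES = list("ADEFGHILMNQSTVWY")  # no K/R/P/C inside peptides


def _synthetic_peptide(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(_RESIDUES, size=length - 1))
    return body + str(rng.choice(["K", "R"]))


def _build() -> tuple[list[tuple[str, str]], dict[str, str], dict[str, float]]:
    rng = np.random.default_rng(_SEED)
    targets: list[tuple[str, str]] = []
    proteome: dict[str, str] = {}
    irt: dict[str, float] = {}
    for marker in MARKERS:
        peptides = [
            _synthetic_peptide(rng, int(rng.integers(8, 13))) for _ in range(4)
        ]
        sequence = "".join(peptides)
        targets.append((marker, sequence))
        proteome[marker] = sequence
        for pep in peptides:
            irt[pep] = float(np.round(rng.uniform(5.0, 95.0), 2))
    # decoys: unrelated background entries
    for i in range(3):
        proteome[f"DECOY{i + 1}"] = "".join(
            _synthetic_peptide(rng, int(rng.integers(8, 13))) for _ in range(5)
        )
    # NANOG-like: all of its tryptic peptides shared with a paralogue
    nanog = "".join(_synthetic_peptide(rng, 9) for _ in range(3))
    proteome["NANOG"] = nanog
    proteome["NANOGP"] = nanog + _synthetic_peptide(rng, 10)
    return targets, proteome, irt


_TARGETS, _PROTEOME, _IRT = _build()


def default_targets(include_nanog: bool = False) -> list[tuple[str, str]]:
    """Synthetic target list: the ten markers (optionally plus NANOG)."""
    targets = list(_TARGETS)
    if include_nanog:
        targets.append(("NANOG", _PROTEOME["NANOG"]))
    return targets


def default_proteome() -> dict[str, str]:
    """Synthetic reference proteome: markers, decoys, NANOG paralogue pair."""
    return dict(_PROTEOME)


def default_irt() -> dict[str, float]:
    """Synthetic iRT score per panel peptide (dimensionless, 5-95)."""
    return dict(_IRT)


def default_panel(
    config: DesignConfig | None = None, include_nanog: bool = False
) -> ProteinPanel:
    """Build the shipped synthetic 10-marker panel.

    Uses default fragment ranking (no spectral library) and attaches the
    synthetic iRT scores needed for scheduled acquisition. The shipped
    panel carries 6 transitions per peptide (within the 4-10 rule): with
    4 peptides per marker and heavy twins this keeps the worst-case
    scheduled concurrency, hence the effective cycle time, inside the
    1.7 s budget at 4-min windows on a 30-min gradient.
    """
    config = config or DesignConfig(max_transitions_per_peptide=6)
    return build_panel(
        default_targets(include_nanog=include_nanog),
        proteome=default_proteome(),
        config=config,
        irt_by_peptide=default_irt(),
    )


def peptides_of(marker: str) -> list[str]:
    """Tryptic peptides of one synthetic marker sequence."""
    return digest_protein(dict(_TARGETS)[marker])
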
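"""Multiplexed SRM assay design.

Builds a validated selected-reaction-monitoring panel for a set of target
proteins: in-silico tryptic digestion, proteotypicity screening against a
reference proteome, monoisotopic precursor and b/y fragment m/z for light
and stable-isotope-labelled (heavy) peptides, transition enumeration by
fragment-intensity rank, and panel-rule validation (each validated protein
carries 2-8 proteotypic peptides, each peptide its 4-10 best transitions).

Masses are monoisotopic throughout. The heavy label is a C-terminal
SIL lysine (+8.014199 Da) or arginine (+10.008269 Da), so the label shifts
the precursor and every y ion but never a b ion.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "PROTON",
    "WATER",
    "CARBAMIDOMETHYL",
    "HEAVY_SHIFTS",
    "MONOISOTOPIC",
    "DesignConfig",
    "PeptideSpec",
    "TransitionAssay",
    "PanelPeptide",
    "PanelProtein",
    "ProteinPanel",
    "PanelValidationReport",
    "digest_protein",
    "check_proteotypic",
    "peptide_mz",
    "fragment_mz",
    "default_fragment_ranks",
    "enumerate_transitions",
    "build_panel",
    "validate_panel",
    "read_fasta",
    "write_transition_list",
    "read_transition_list",
    "read_rank_table",
]

PROTON = 1.007276  # Da, mass of a proton
WATER = 18.010565  # Da, monoisotopic H2O
CARBAMIDOMETHYL = 57.021464  # Da, iodoacetamide-derived fixed mod on Cys

# SIL C-terminal labels used for heavy reference peptides
HEAVY_SHIFTS = {"K": 8.014199, "R": 10.008269}

# Monoisotopic residue masses (Da), 20 canonical amino acids
MONOISOTOPIC = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009184,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

_FRAGMENT_RE = re.compile(r"^([by])(\d+)$")


class DesignError(ValueError):
    """Invalid input to an assay-design operation."""


@dataclass(frozen=True)
class DesignConfig:
    """Panel-design rules and physical constants of the assay.

    Defaults encode the published method: doubly and triply charged
    precursors, singly and doubly charged b/y fragments, the 20 most
    probable fragments carried through development, final panels with
    2-8 peptides per protein and 4-10 transitions per peptide.
    """

    precursor_charges: tuple[int, ...] = (2, 3)
    fragment_charges: tuple[int, ...] = (1, 2)
    top_n_fragments: int = 20
    min_peptides_per_protein: int = 2
    max_peptides_per_protein: int = 8
    min_transitions_per_peptide: int = 4
    max_transitions_per_peptide: int = 10
    heavy_shifts: Mapping[str, float] = field(
        default_factory=lambda: dict(HEAVY_SHIFTS)
    )
    missed_cleavages: int = 0
    proline_rule: bool = True
    # SRM detectability convention for candidate peptides
    min_peptide_length: int = 7
    max_peptide_length: int = 25

    def __post_init__(self) -> None:
        if self.min_peptides_per_protein > self.max_peptides_per_protein:
            raise DesignError("min peptides per protein exceeds max")
        if self.min_transitions_per_peptide > self.max_transitions_per_peptide:
            raise DesignError("min transitions per peptide exceeds max")
        if self.top_n_fragments < self.max_transitions_per_peptide:
            raise DesignError(
                "top_n_fragments must be >= max transitions per peptide"
            )
        if self.missed_cleavages < 0:
            raise DesignError("missed_cleavages must be >= 0")


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise DesignError("peptide/protein sequence is empty")
    for pos, ch in enumerate(sequence):
        if ch not in MONOISOTOPIC:
            raise DesignError(
                f"non-canonical residue {ch!r} at position {pos + 1}"
            )


@dataclass(frozen=True)
class PeptideSpec:
    """One light or heavy peptide targeted by the assay."""

    protein_id: str
    sequence: str
    label_state: str = "light"  # "light" | "heavy"
    heavy_shift: float = 0.0
    irt: Optional[float] = None
    fixed_mods: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.label_state not in ("light", "heavy"):
            raise DesignError(f"unknown label_state {self.label_state!r}")
        if self.label_state == "heavy":
            if self.heavy_shift <= 0:
                raise DesignError("heavy peptide requires heavy_shift > 0")
            if self.sequence[-1] not in ("K", "R"):
                raise DesignError(
                    "heavy peptide must end in K or R (tryptic C-terminus)"
                )
        elif self.heavy_shift != 0:
            raise DesignError("light peptide must have heavy_shift == 0")

    def as_heavy(self, shifts: Mapping[str, float] | None = None) -> "PeptideSpec":
        """Return the heavy SIL twin of a light peptide."""
        if self.label_state == "heavy":
            return self
        shifts = dict(shifts or HEAVY_SHIFTS)
        cterm = self.sequence[-1]
        if cterm not in shifts:
            raise DesignError(
                f"no heavy label defined for C-terminal residue {cterm!r}"
            )
        return dataclasses.replace(
            self, label_state="heavy", heavy_shift=shifts[cterm]
        )

    def _mod_mass(self, residues: str) -> float:
        return sum(
            shift * residues.count(res) for res, shift in self.fixed_mods
        )

    def neutral_mass(self) -> float:
        """Monoisotopic neutral mass including fixed mods and label."""
        return (
            sum(MONOISOTOPIC[r] for r in self.sequence)
            + self._mod_mass(self.sequence)
            + self.heavy_shift
            + WATER
        )


@dataclass(frozen=True)
class TransitionAssay:
    """One precursor -> fragment pair monitored by the instrument."""

    peptide: PeptideSpec
    precursor_charge: int
    fragment_series: str  # "b" | "y"
    fragment_index: int
    fragment_charge: int
    precursor_mz: float
    product_mz: float
    rank: int

    def __post_init__(self) -> None:
        n = len(self.peptide.sequence)
        if not 1 <= self.fragment_index <= n - 1:
            raise DesignError(
                f"fragment index {self.fragment_index} out of range for "
                f"{n}-residue peptide"
            )
        if self.fragment_series not in ("b", "y"):
            raise DesignError(f"unknown series {self.fragment_series!r}")
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise DesignError("m/z must be positive")
        if self.rank < 1:
            raise DesignError("rank must be a positive integer")

    @property
    def fragment(self) -> str:
        return f"{self.fragment_series}{self.fragment_index}"

    @property
    def label_state(self) -> str:
        return self.peptide.label_state

    def coordinates(self) -> tuple:
        """Label-free identity of the transition within a panel."""
        return (
            self.peptide.sequence,
            self.precursor_charge,
            self.fragment_series,
            self.fragment_index,
            self.fragment_charge,
        )


def peptide_mz(peptide: PeptideSpec, charge: int) -> float:
    """Precursor m/z of a (possibly heavy) peptide at the given charge."""
    if charge < 1:
        raise DesignError(f"charge must be >= 1, got {charge}")
    return (peptide.neutral_mass() + charge * PROTON) / charge


def fragment_mz(
    peptide: PeptideSpec, series: str, index: int, charge: int
) -> float:
    """m/z of the b_index or y_index fragment ion.

    y_i covers the i C-terminal residues (so the heavy C-terminal label
    shifts every y ion); b_i covers the i N-terminal residues and is
    label-invariant.
    """
    if charge < 1:
        raise DesignError(f"charge must be >= 1, got {charge}")
    seq = peptide.sequence
    n = len(seq)
    if not 1 <= index <= n - 1:
        raise DesignError(
            f"fragment index {index} out of range 1..{n - 1} for {seq!r}"
        )
    if series == "b":
        part = seq[:index]
        neutral = (
            sum(MONOISOTOPIC[r] for r in part) + peptide._mod_mass(part)
        )
    elif series == "y":
        part = seq[n - index:]
        neutral = (
            sum(MONOISOTOPIC[r] for r in part)
            + peptide._mod_mass(part)
            + peptide.heavy_shift
            + WATER
        )
    else:
        raise DesignError(f"unknown fragment series {series!r}")
    return (neutral + charge * PROTON) / charge


def digest_protein(sequence: str, config: DesignConfig | None = None) -> list[str]:
    """In-silico trypsin/LysC digest: cleave after K/R, not before P.

    Returns fully cleaved peptides in N->C order, followed by
    missed-cleavage products when ``config.missed_cleavages`` > 0.
    """
    config = config or DesignConfig()
    _check_sequence(sequence)
    fragments: list[str] = []
    start = 0
    for i, res in enumerate(sequence):
        if res in ("K", "R") and i + 1 < len(sequence):
            if config.proline_rule and sequence[i + 1] == "P":
                continue
            fragments.append(sequence[start : i + 1])
            start = i + 1
    fragments.append(sequence[start:])
    peptides = list(fragments)
    for mc in range(1, config.missed_cleavages + 1):
        for j in range(len(fragments) - mc):
            peptides.append("".join(fragments[j : j + mc + 1]))
    return peptides


def check_proteotypic(peptide: str, proteome: Mapping[str, str]) -> bool:
    """True iff the peptide occurs in exactly one proteome entry.

    A peptide absent from the proteome is not proteotypic: targets must
    exist in the reference against which specificity is claimed.
    """
    if not peptide:
        raise DesignError("empty peptide")
    if not proteome:
        raise DesignError("empty proteome")
    hits = sum(1 for seq in proteome.values() if peptide in seq)
    return hits == 1


def default_fragment_ranks(
    peptide: PeptideSpec, config: DesignConfig | None = None
) -> dict[tuple[str, int], int]:
    """Deterministic fallback ranking when no spectral library is given.

    y ions rank ahead of b ions, longer fragments ahead of shorter,
    singly charged ahead of doubly charged — the usual intensity order
    for tryptic peptides at low collision energy.
    """
    config = config or DesignConfig()
    n = len(peptide.sequence)
    ordered: list[tuple[str, int]] = []
    for charge in sorted(config.fragment_charges):
        for series in ("y", "b"):
            for index in range(n - 1, 0, -1):
                ordered.append((f"{series}{index}", charge))
    return {key: rank for rank, key in enumerate(ordered, start=1)}


def _parse_fragment(fragment: str) -> tuple[str, int]:
    m = _FRAGMENT_RE.match(fragment)
    if not m:
        raise DesignError(f"cannot parse fragment id {fragment!r}")
    return m.group(1), int(m.group(2))


def _sort_key(item: tuple[tuple[str, int], int]) -> tuple:
    (fragment, charge), rank = item
    series, index = _parse_fragment(fragment)
    # ties: y before b, lower index first, lower fragment charge first
    return (rank, 0 if series == "y" else 1, index, charge)


def enumerate_transitions(
    peptide: PeptideSpec,
    fragment_ranks: Mapping[tuple[str, int], int] | None,
    config: DesignConfig | None = None,
    top_n: int | None = None,
) -> list[TransitionAssay]:
    """Enumerate ranked light/heavy transition pairs for one peptide.

    For each configured precursor charge, the ``top_n`` (default
    ``config.top_n_fragments``) best-ranked b/y fragments are emitted,
    each as a light assay immediately followed by its heavy twin with
    identical fragment coordinates.
    """
    config = config or DesignConfig()
    if top_n is None:
        top_n = config.top_n_fragments
    light = peptide if peptide.label_state == "light" else None
    if light is None:
        raise DesignError("enumerate_transitions expects a light peptide")
    if fragment_ranks is None:
        fragment_ranks = default_fragment_ranks(peptide, config)
    n = len(peptide.sequence)
    candidates = {}
    for (fragment, charge), rank in fragment_ranks.items():
        series, index = _parse_fragment(fragment)
        if not 1 <= index <= n - 1 or charge not in config.fragment_charges:
            continue
        candidates[(fragment, charge)] = int(rank)
    if not candidates:
        raise DesignError(
            f"no rankable fragments for peptide {peptide.sequence!r}"
        )
    ordered = sorted(candidates.items(), key=_sort_key)[:top_n]
    heavy = peptide.as_heavy(config.heavy_shifts)
    out: list[TransitionAssay] = []
    for precursor_charge in sorted(config.precursor_charges):
        for (fragment, fcharge), rank in ordered:
            series, index = _parse_fragment(fragment)
            for spec in (light, heavy):
                out.append(
                    TransitionAssay(
                        peptide=spec,
                        precursor_charge=precursor_charge,
                        fragment_series=series,
                        fragment_index=index,
                        fragment_charge=fcharge,
                        precursor_mz=peptide_mz(spec, precursor_charge),
                        product_mz=fragment_mz(spec, series, index, fcharge),
                        rank=rank,
                    )
                )
    return out


@dataclass
class PanelPeptide:
    """A panel peptide with its selected light+heavy transitions."""

    spec: PeptideSpec
    transitions: list[TransitionAssay]

    @property
    def n_transitions(self) -> int:
        """Distinct label-free transition coordinates."""
        return len({t.coordinates() for t in self.transitions})


@dataclass
class PanelProtein:
    protein_id: str
    peptides: list[PanelPeptide]


@dataclass
class ProteinPanel:
    """Validated marker panel: proteins -> peptides -> transitions."""

    proteins: list[PanelProtein]
    config: DesignConfig
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def all_transitions(self) -> list[TransitionAssay]:
        return [
            t
            for prot in self.proteins
            for pep in prot.peptides
            for t in pep.transitions
        ]

    @property
    def n_transitions(self) -> int:
        return len(self.all_transitions())


def build_panel(
    targets: Sequence[tuple[str, str]],
    proteome: Mapping[str, str] | None = None,
    library_ranks: Mapping[str, Mapping[tuple[str, int], int]] | None = None,
    config: DesignConfig | None = None,
    irt_by_peptide: Mapping[str, float] | None = None,
) -> ProteinPanel:
    """Assemble a multiplexed panel from target protein sequences.

    Per target: digest, keep candidate peptides 7-25 residues long
    (and proteotypic when a proteome is supplied), rank peptides by the
    summed ranks of their best fragments, keep at most
    ``max_peptides_per_protein``, and attach each peptide's
    ``max_transitions_per_peptide`` best transitions (light+heavy pairs)
    at the lowest configured precursor charge. Targets that cannot meet
    the minimum-peptide rule are excluded with a reason.
    """
    config = config or DesignConfig()
    if not targets:
        raise DesignError("empty target list")
    proteins: list[PanelProtein] = []
    excluded: list[tuple[str, str]] = []
    panel_charge = min(config.precursor_charges)
    for protein_id, sequence in targets:
        peptides = digest_protein(sequence, config)
        candidates = [
            p
            for p in dict.fromkeys(peptides)
            if config.min_peptide_length <= len(p) <= config.max_peptide_length
            and p[-1] in config.heavy_shifts
        ]
        if proteome is not None:
            candidates = [
                p for p in candidates if check_proteotypic(p, proteome)
            ]
            if not candidates:
                excluded.append((protein_id, "no proteotypic peptides"))
                continue
        if len(candidates) < config.min_peptides_per_protein:
            excluded.append(
                (
                    protein_id,
                    f"only {len(candidates)} candidate peptide(s), "
                    f"need >= {config.min_peptides_per_protein}",
                )
            )
            continue

        scored: list[tuple[float, int, str]] = []
        for pos, pep_seq in enumerate(candidates):
            spec = PeptideSpec(
                protein_id=protein_id,
                sequence=pep_seq,
                irt=(irt_by_peptide or {}).get(pep_seq),
            )
            ranks = (library_ranks or {}).get(pep_seq)
            if ranks is None:
                ranks = default_fragment_ranks(spec, config)
            usable = sorted(
                enumerate_transitions(
                    spec, ranks, config, top_n=config.top_n_fragments
                ),
                key=lambda t: t.rank,
            )
            n_coords = len(
                {
                    t.coordinates()
                    for t in usable
                    if t.precursor_charge == panel_charge
                }
            )
            if n_coords < config.min_transitions_per_peptide:
                continue
            top = sorted(ranks.values())[: config.min_transitions_per_peptide]
            scored.append((float(sum(top)), pos, pep_seq))
        if len(scored) < config.min_peptides_per_protein:
            excluded.append(
                (
                    protein_id,
                    f"only {len(scored)} peptide(s) with >= "
                    f"{config.min_transitions_per_peptide} transitions",
                )
            )
            continue
        scored.sort()
        chosen = scored[: config.max_peptides_per_protein]
        chosen.sort(key=lambda s: s[1])  # restore N->C order

        panel_peptides: list[PanelPeptide] = []
        for _, _, pep_seq in chosen:
            spec = PeptideSpec(
                protein_id=protein_id,
                sequence=pep_seq,
                irt=(irt_by_peptide or {}).get(pep_seq),
            )
            ranks = (library_ranks or {}).get(pep_seq)
            if ranks is None:
                ranks = default_fragment_ranks(spec, config)
            charge_config = dataclasses.replace(
                config, precursor_charges=(panel_charge,)
            )
            transitions = enumerate_transitions(
                spec,
                ranks,
                charge_config,
                top_n=config.max_transitions_per_peptide,
            )
            panel_peptides.append(PanelPeptide(spec=spec, transitions=transitions))
        proteins.append(PanelProtein(protein_id=protein_id, peptides=panel_peptides))
    if not proteins:
        reasons = "; ".join(f"{pid}: {why}" for pid, why in excluded)
        raise DesignError(f"all targets excluded — {reasons}")
    return ProteinPanel(proteins=proteins, config=config, excluded=excluded)


@dataclass
class PanelValidationReport:
    """Per-protein pass/fail against the panel-design rules."""

    entries: list[dict]
    valid: bool

    def failures(self) -> list[dict]:
        return [e for e in self.entries if e["failures"]]


def validate_panel(panel: ProteinPanel) -> PanelValidationReport:
    """Check every protein/peptide against the DesignConfig bounds.

    Transition counts are label-free coordinates (a light/heavy pair
    counts once, mirroring how assays are reported).
    """
    cfg = panel.config
    entries = []
    for prot in panel.proteins:
        failures = []
        n_pep = len(prot.peptides)
        if n_pep < cfg.min_peptides_per_protein:
            failures.append("min peptides")
        if n_pep > cfg.max_peptides_per_protein:
            failures.append("max peptides")
        counts = {}
        for pep in prot.peptides:
            n_tr = pep.n_transitions
            counts[pep.spec.sequence] = n_tr
            if n_tr < cfg.min_transitions_per_peptide:
                failures.append(f"min transitions ({pep.spec.sequence})")
            if n_tr > cfg.max_transitions_per_peptide:
                failures.append(f"max transitions ({pep.spec.sequence})")
        entries.append(
            {
                "protein_id": prot.protein_id,
                "n_peptides": n_pep,
                "transition_counts": counts,
                "failures": failures,
            }
        )
    return PanelValidationReport(
        entries=entries, valid=all(not e["failures"] for e in entries)
    )


# ---------------------------------------------------------------------------
# External interfaces


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a proteome FASTA; first token of the description is the id."""
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        proteome[record.id.split()[0]] = str(record.seq).upper()
    if not proteome:
        raise DesignError(f"no FASTA records in {path}")
    return proteome


_TRANSITION_COLUMNS = [
    "protein",
    "peptide_sequence",
    "label",
    "precursor_mz",
    "precursor_charge",
    "fragment",
    "fragment_charge",
    "product_mz",
    "irt",
    "rank",
]


def panel_to_frame(panel: ProteinPanel) -> pd.DataFrame:
    rows = []
    for prot in panel.proteins:
        for pep in prot.peptides:
            for t in pep.transitions:
                rows.append(
                    {
                        "protein": prot.protein_id,
                        "peptide_sequence": t.peptide.sequence,
                        "label": t.label_state,
                        "precursor_mz": round(t.precursor_mz, 4),
                        "precursor_charge": t.precursor_charge,
                        "fragment": t.fragment,
                        "fragment_charge": t.fragment_charge,
                        "product_mz": round(t.product_mz, 4),
                        "irt": t.peptide.irt,
                        "rank": t.rank,
                    }
                )
    return pd.DataFrame(rows, columns=_TRANSITION_COLUMNS)


def write_transition_list(panel: ProteinPanel, path: str | Path) -> pd.DataFrame:
    frame = panel_to_frame(panel)
    frame.to_csv(path, index=False, float_format="%.4f")
    return frame


def read_transition_list(
    path: str | Path, config: DesignConfig | None = None
) -> ProteinPanel:
    """Rebuild a ProteinPanel from a transition-list CSV."""
    config = config or DesignConfig()
    frame = pd.read_csv(path)
    missing = [c for c in _TRANSITION_COLUMNS if c not in frame.columns]
    if missing:
        raise DesignError(f"transition list missing column(s): {missing}")
    proteins: dict[str, dict[str, PanelPeptide]] = {}
    for (protein, pep_seq), grp in frame.groupby(
        ["protein", "peptide_sequence"], sort=False
    ):
        irt_vals = grp["irt"].dropna().unique()
        irt = float(irt_vals[0]) if len(irt_vals) else None
        light = PeptideSpec(protein_id=protein, sequence=pep_seq, irt=irt)
        heavy = light.as_heavy(config.heavy_shifts)
        transitions = []
        for _, row in grp.iterrows():
            spec = light if row["label"] == "light" else heavy
            series, index = _parse_fragment(row["fragment"])
            transitions.append(
                TransitionAssay(
                    peptide=spec,
                    precursor_charge=int(row["precursor_charge"]),
                    fragment_series=series,
                    fragment_index=index,
                    fragment_charge=int(row["fragment_charge"]),
                    precursor_mz=float(row["precursor_mz"]),
                    product_mz=float(row["product_mz"]),
                    rank=int(row["rank"]),
                )
            )
        proteins.setdefault(protein, {})[pep_seq] = PanelPeptide(
            spec=light, transitions=transitions
        )
    return ProteinPanel(
        proteins=[
            PanelProtein(protein_id=pid, peptides=list(peps.values()))
            for pid, peps in proteins.items()
        ],
        config=config,
    )


def read_rank_table(path: str | Path) -> dict[str, dict[tuple[str, int], int]]:
    """Read a spectral-library rank CSV.

    Columns: peptide_sequence, fragment, fragment_charge, rank.
    """
    frame = pd.read_csv(path)
    required = ["peptide_sequence", "fragment", "fragment_charge", "rank"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DesignError(f"rank table missing column(s): {missing}")
    ranks: dict[str, dict[tuple[str, int], int]] = {}
    for _, row in frame.iterrows():
        ranks.setdefault(row["peptide_sequence"], {})[
            (row["fragment"], int(row["fragment_charge"]))
        ] = int(row["rank"])
    return ranks
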
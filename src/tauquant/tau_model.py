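"""Sequence-level model of Tau isoforms.

Provides isoform loading with cross-isoform coordinate maps, point-mutation
application, in-silico tryptic digestion with canonical-numbered peptide
coordinates, and species/isoform specificity classification of peptides.

All residue coordinates are 1-based and, unless stated otherwise, expressed
in canonical 2N4R (441-residue) numbering. Site names follow the
``<prefix><residue><canonical position>`` convention (e.g. ``pT212``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "CANONICAL_ISOFORM",
    "CANONICAL_LENGTH",
    "FLEX_TAG",
    "EnzymeRule",
    "Peptide",
    "SpeciesSet",
    "TauIsoform",
    "annotate_specificity",
    "apply_mutation",
    "build_panel",
    "classify_peptide",
    "default_species_set",
    "digest",
    "load_isoform",
    "map_position",
    "write_digest_tsv",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Reporter peptide carried by the heavy full-length standard; a known light
#: synthetic spike of this sequence calibrates the standard amount.
FLEX_TAG = "SENLYFQGDISR"

CANONICAL_ISOFORM = "2N4R"
CANONICAL_LENGTH = 441

# Canonical regions absent from shorter isoforms: the two N-terminal inserts.
# 0N isoforms lack both, 1N isoforms lack only the first.
_INSERT_1 = (45, 73)
_INSERT_2 = (74, 102)

_DELETED_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "2N4R": (),
    "1N4R": (_INSERT_2,),
    "0N4R": (_INSERT_1, _INSERT_2),
    "MOUSE": (),  # vendored mouse fixture is aligned residue-for-residue to 2N4R
}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class TauIsoform:
    """A named Tau sequence plus its map into canonical 2N4R numbering.

    ``canonical_map[i]`` is the canonical position (1-based) of residue
    ``i + 1`` of this isoform. Positions absent from the isoform (e.g. the
    N-terminal inserts in 0N isoforms) simply do not appear in the map.
    """

    name: str
    sequence: str
    canonical_map: tuple[int, ...]
    mutations: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.name}: non-standard residues {sorted(bad)}")
        if len(self.sequence) != len(self.canonical_map):
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"{len(self.canonical_map)} mapped positions"
            )
        if any(b <= a for a, b in zip(self.canonical_map, self.canonical_map[1:])):
            raise ValueError(f"{self.name}: canonical_map must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)

    def local_position(self, canonical_pos: int) -> int | None:
        """Local 1-based position of a canonical position, or None if absent."""
        try:
            return self.canonical_map.index(canonical_pos) + 1
        except ValueError:
            return None

    def residue_at_canonical(self, canonical_pos: int) -> str | None:
        local = self.local_position(canonical_pos)
        return None if local is None else self.sequence[local - 1]


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with canonical (2N4R) interval coordinates.

    For peptides of short isoforms that span an insert junction, ``start``
    and ``end`` are the canonical coordinates of the first and last residues
    actually present.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int = 0
    specificity: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"peptide {self.sequence}: start {self.start} > end {self.end}")

    @property
    def interval(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage rule. Default: trypsin — cut after K/R unless followed by P."""

    cleave_after: frozenset[str] = frozenset("KR")
    blocked_by_next: frozenset[str] = frozenset("P")
    max_missed: int = 0

    def cut_points(self, sequence: str) -> list[int]:
        """0-based indices *after* which the chain is cut (excludes the end)."""
        cuts = []
        for i, aa in enumerate(sequence[:-1]):
            if aa in self.cleave_after and sequence[i + 1] not in self.blocked_by_next:
                cuts.append(i)
        return cuts


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("tauquant.data").joinpath(filename)))


def _read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _canonical_map_for(name: str, length: int) -> tuple[int, ...]:
    deleted = _DELETED_RANGES[name]
    absent: set[int] = set()
    for lo, hi in deleted:
        absent.update(range(lo, hi + 1))
    mapping = tuple(p for p in range(1, CANONICAL_LENGTH + 1) if p not in absent)
    if len(mapping) != length:
        raise ValueError(
            f"{name}: sequence length {length} inconsistent with insert table "
            f"({len(mapping)} expected)"
        )
    return mapping


def load_isoform(name: str, fasta: Path | str | None = None) -> TauIsoform:
    """Load a Tau isoform by name, optionally with trailing mutation specs.

    ``name`` is a base isoform identifier (``2N4R``, ``1N4R``, ``0N4R``,
    ``MOUSE``), optionally suffixed with dash-separated mutations, e.g.
    ``"0N4R-P301L"``. Sequences come from the vendored fixture FASTA unless
    ``fasta`` points at a user-supplied file with matching record ids.
    """
    parts = name.split("-")
    base, mut_specs = parts[0], parts[1:]
    sequences = _read_fasta(fasta if fasta is not None else _data_path("tau_isoforms.fasta"))
    if base not in sequences:
        raise KeyError(f"unknown isoform {base!r}; available: {sorted(sequences)}")
    if base not in _DELETED_RANGES:
        raise KeyError(f"no coordinate table for isoform {base!r}")
    seq = sequences[base]
    iso = TauIsoform(name=base, sequence=seq, canonical_map=_canonical_map_for(base, len(seq)))
    for spec in mut_specs:
        iso = apply_mutation(iso, spec)
    return iso


def apply_mutation(iso: TauIsoform, spec: str) -> TauIsoform:
    """Apply a point mutation given in canonical numbering, e.g. ``"P301S"``.

    The reference residue must match the isoform at the mapped local
    position; mutations at canonical positions absent from the isoform are
    rejected.
    """
    m = _MUTATION_RE.match(spec)
    if not m:
        raise ValueError(f"malformed mutation spec {spec!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    if ref == alt:
        raise ValueError(f"{spec}: alternate residue equals reference")
    if alt not in AMINO_ACIDS:
        raise ValueError(f"{spec}: non-standard alternate residue")
    local = iso.local_position(pos)
    if local is None:
        raise ValueError(f"{spec}: canonical position {pos} absent from isoform {iso.name}")
    have = iso.sequence[local - 1]
    if have != ref:
        raise ValueError(f"{spec}: isoform {iso.name} has {have} at canonical {pos}, not {ref}")
    seq = iso.sequence[: local - 1] + alt + iso.sequence[local:]
    return replace(
        iso,
        name=f"{iso.name}-{spec}",
        sequence=seq,
        mutations=iso.mutations + ((pos, ref, alt),),
    )


def digest(iso: TauIsoform, rule: EnzymeRule | None = None) -> list[Peptide]:
    """In-silico digest of an isoform into canonical-numbered peptides.

    At 0 missed cleavages the peptides tile the sequence without gaps; with
    ``rule.max_missed > 0`` every contiguous concatenation of up to
    ``max_missed + 1`` adjacent fragments is also included. Peptides are
    ordered by start coordinate, then by missed-cleavage count.
    """
    rule = rule or EnzymeRule()
    seq = iso.sequence
    if not seq:
        return []
    cuts = rule.cut_points(seq)
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    fragments = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    peptides: list[Peptide] = []
    for i in range(len(fragments)):
        for missed in range(rule.max_missed + 1):
            j = i + missed
            if j >= len(fragments):
                break
            lo, hi = fragments[i][0], fragments[j][1]
            peptides.append(
                Peptide(
                    sequence=seq[lo:hi],
                    start=iso.canonical_map[lo],
                    end=iso.canonical_map[hi - 1],
                    missed_cleavages=missed,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.missed_cleavages))
    return peptides


def map_position(pos: int, from_iso: TauIsoform, to_iso: TauIsoform) -> int | None:
    """Map a local residue position between isoforms via canonical numbering.

    Returns the local 1-based position in ``to_iso`` or ``None`` when the
    residue falls in a region absent from the target isoform.
    """
    if not 1 <= pos <= len(from_iso):
        raise ValueError(f"position {pos} outside isoform {from_iso.name} (1..{len(from_iso)})")
    canonical = from_iso.canonical_map[pos - 1]
    return to_iso.local_position(canonical)


@dataclass(frozen=True)
class SpeciesSet:
    """The sequence universe used to classify peptide specificity.

    ``human`` is the (possibly mutant) human transgene; ``wildtype_human``
    the unmutated counterpart used to separate mutant-specific from
    human-specific peptides; ``mouse`` the endogenous mouse Tau.
    """

    human: TauIsoform
    mouse: TauIsoform
    wildtype_human: TauIsoform | None = None
    classification_missed: int = 2

    def _pepset(self, iso: TauIsoform) -> frozenset[str]:
        rule = EnzymeRule(max_missed=self.classification_missed)
        return frozenset(p.sequence for p in digest(iso, rule))

    def __post_init__(self) -> None:
        object.__setattr__(self, "_human_set", self._pepset(self.human))
        object.__setattr__(self, "_mouse_set", self._pepset(self.mouse))
        wt = self.wildtype_human
        object.__setattr__(self, "_wt_set", self._pepset(wt) if wt is not None else frozenset())


def classify_peptide(pep: Peptide | str, species_set: SpeciesSet) -> str:
    """Classify a peptide as flex_tag / shared / human_specific /
    mutant_specific / mouse_specific against the species sequence set.

    Classification is a pure function of the peptide sequence: membership in
    the tryptic digests (up to ``classification_missed`` missed cleavages)
    of the configured sequences.
    """
    seq = pep.sequence if isinstance(pep, Peptide) else pep
    if seq == FLEX_TAG:
        return "flex_tag"
    in_human = seq in species_set._human_set  # type: ignore[attr-defined]
    in_mouse = seq in species_set._mouse_set  # type: ignore[attr-defined]
    in_wt = seq in species_set._wt_set  # type: ignore[attr-defined]
    if in_human and in_mouse:
        return "shared"
    if in_human:
        if species_set.human.mutations and not in_wt and species_set.wildtype_human is not None:
            return "mutant_specific"
        return "human_specific"
    if in_mouse:
        return "mouse_specific"
    if in_wt:
        # present in wild-type human but lost from the transgene (mutation
        # created/destroyed a cleavage site)
        return "human_specific"
    raise ValueError(f"peptide {seq!r} not found in any configured species digest")


def default_species_set(mutation: str | None = "P301S") -> SpeciesSet:
    """Species set mirroring the transgenic-mouse design: human 0N4R
    transgene (optionally mutated) against endogenous mouse Tau."""
    wt = load_isoform("0N4R")
    human = apply_mutation(wt, mutation) if mutation else wt
    return SpeciesSet(human=human, mouse=load_isoform("MOUSE"), wildtype_human=wt)


def annotate_specificity(
    peptides: Iterable[Peptide], species_set: SpeciesSet
) -> list[Peptide]:
    """Return peptides with their specificity field filled in."""
    return [replace(p, specificity=classify_peptide(p, species_set)) for p in peptides]


def build_panel(
    mutation: str | None = "P301S",
    min_len: int = 6,
    max_len: int = 32,
    include_flex: bool = True,
) -> dict[str, Peptide]:
    """Default quantification panel: fully tryptic transgene (0N4R) peptides
    of length ``min_len``..``max_len`` with specificity annotated, plus the
    flex-tag reporter. Keyed by peptide sequence; user-overridable."""
    species = default_species_set(mutation)
    peptides = [
        p
        for p in digest(species.human, EnzymeRule(max_missed=0))
        if min_len <= len(p.sequence) <= max_len
    ]
    panel = {p.sequence: p for p in annotate_specificity(peptides, species)}
    if include_flex:
        panel[FLEX_TAG] = Peptide(
            sequence=FLEX_TAG, start=0, end=0, missed_cleavages=0, specificity="flex_tag"
        )
    return panel


def write_digest_tsv(peptides: Sequence[Peptide], path: Path | str) -> None:
    """Export a digest as TSV: peptide, start, end, missed_cleavages, specificity."""
    with open(path, "w") as fh:
        fh.write("peptide\tstart\tend\tmissed_cleavages\tspecificity\n")
        for p in peptides:
            fh.write(
                f"{p.sequence}\t{p.start}\t{p.end}\t{p.missed_cleavages}\t"
                f"{p.specificity or ''}\n"
            )
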
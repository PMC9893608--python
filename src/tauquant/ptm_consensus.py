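"""Multi-engine PTM site consensus.

Combines per-search-engine PTM site tables into canonical-numbered
site x condition matrices. Combination is union-at-replicate level: a site
counts in a biological replicate if any engine reports it there. The
frequency of a site in a condition is the fraction of that condition's
replicates with at least one observation; the binary matrix applies an
inclusive frequency threshold (default 0.5).

Engine inputs are assumed already confidence-filtered upstream; readers
only validate residue/modification compatibility and coordinate mappability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .srm_quant import SampleMeta
from .tau_model import CANONICAL_ISOFORM, TauIsoform

logger = logging.getLogger(__name__)

__all__ = [
    "ENGINE_DIALECTS",
    "MOD_RESIDUES",
    "MOD_PREFIX",
    "PtmSite",
    "PtmSiteMatrix",
    "SiteObservation",
    "binary_ptm_matrix",
    "read_engine_sites",
    "register_engine_dialect",
    "site_frequency",
    "to_canonical_sites",
]

#: Residues each modification type may occupy.
MOD_RESIDUES: dict[str, str] = {
    "phospho": "STY",
    "ubiquitin": "K",
    "acetyl": "K",
    "methyl": "KR",
    "citrullination": "R",
    "oxidation": "M",
}

#: Display-name prefixes, e.g. pT212, cR155, ubK259.
MOD_PREFIX: dict[str, str] = {
    "phospho": "p",
    "citrullination": "c",
    "ubiquitin": "ub",
    "acetyl": "ac",
    "methyl": "me",
    "oxidation": "ox",
}

#: Normalization of engine-specific modification vocabulary.
_MOD_SYNONYMS: dict[str, str] = {
    "phospho": "phospho",
    "phosphorylation": "phospho",
    "phospho (sty)": "phospho",
    "phospho (st)": "phospho",
    "glygly": "ubiquitin",
    "glygly (k)": "ubiquitin",
    "ubiquitin": "ubiquitin",
    "ubiquitination": "ubiquitin",
    "acetyl": "acetyl",
    "acetyl (k)": "acetyl",
    "acetylation": "acetyl",
    "methyl": "methyl",
    "methyl (kr)": "methyl",
    "methylation": "methyl",
    "citrullination": "citrullination",
    "citrullination (r)": "citrullination",
    "oxidation": "oxidation",
    "oxidation (m)": "oxidation",
}

#: Per-engine column dialects: logical name -> actual header.
ENGINE_DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "sample_id": "sample_id",
        "peptide": "peptide",
        "position": "position",
        "residue": "residue",
        "mod_type": "mod_type",
    },
    "mascot": {
        "sample_id": "query_file",
        "peptide": "pep_seq",
        "position": "site_position",
        "residue": "site_residue",
        "mod_type": "modification",
    },
    "maxquant": {
        "sample_id": "Raw file",
        "peptide": "Sequence",
        "position": "Position",
        "residue": "Amino acid",
        "mod_type": "Modification",
    },
    "proteinpilot": {
        "sample_id": "Sample",
        "peptide": "Peptide",
        "position": "Mod Position",
        "residue": "Mod Residue",
        "mod_type": "Mod Name",
    },
    "fragpipe": {
        "sample_id": "Spectrum File",
        "peptide": "Peptide Sequence",
        "position": "Protein Site",
        "residue": "Site Residue",
        "mod_type": "Assigned Modification",
    },
}


def register_engine_dialect(engine: str, column_map: Mapping[str, str]) -> None:
    """Register (or override) a column dialect for an engine id."""
    required = {"sample_id", "peptide", "position", "residue", "mod_type"}
    missing = required - set(column_map)
    if missing:
        raise ValueError(f"dialect for {engine!r} missing logical columns {missing}")
    ENGINE_DIALECTS[engine] = dict(column_map)


@dataclass(frozen=True)
class SiteObservation:
    """One engine's report of a modified residue in one sample, in the
    search-database protein's local coordinates."""

    engine: str
    sample_id: str
    peptide: str
    local_position: int
    mod_type: str
    residue: str

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_RESIDUES:
            raise ValueError(f"unknown modification type {self.mod_type!r}")
        if self.residue not in MOD_RESIDUES[self.mod_type]:
            raise ValueError(
                f"{self.mod_type} not allowed on residue {self.residue!r}"
            )


@dataclass(frozen=True, order=True)
class PtmSite:
    """A modification site in canonical 2N4R numbering."""

    canonical_position: int
    residue: str
    mod_type: str

    @property
    def display(self) -> str:
        return f"{MOD_PREFIX[self.mod_type]}{self.residue}{self.canonical_position}"


@dataclass
class PtmSiteMatrix:
    """Sites x conditions matrix; ``frequency`` holds replicate fractions in
    [0, 1]; ``binary`` (if materialized) is the thresholded presence form."""

    frequency: pd.DataFrame
    sites: dict[str, PtmSite] = field(default_factory=dict)
    threshold: float | None = None
    binary: pd.DataFrame | None = None

    def to_tsv(self, path: Path | str, binary: bool = False) -> None:
        df = self.binary if binary else self.frequency
        if df is None:
            raise ValueError("binary form not materialized")
        df.to_csv(path, sep="\t", index_label="site")


def _normalize_mod(raw: str) -> str | None:
    return _MOD_SYNONYMS.get(str(raw).strip().lower())


def read_engine_sites(
    path: Path | str,
    engine: str,
    database_isoform: TauIsoform,
    sep: str | None = None,
) -> tuple[list[SiteObservation], int]:
    """Read one engine's PTM site table into validated observations.

    Rows are rejected (with a log line and a count) when the modification is
    unknown, incompatible with its residue, the position is ambiguous
    (non-integer), or the stated residue disagrees with the search-database
    isoform sequence.
    """
    if engine not in ENGINE_DIALECTS:
        raise KeyError(f"unknown engine dialect {engine!r}")
    colmap = ENGINE_DIALECTS[engine]
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} for engine {engine}")
    observations: list[SiteObservation] = []
    n_rejected = 0
    for _, row in df.iterrows():
        raw_pos = str(row[colmap["position"]]).strip()
        mod = _normalize_mod(row[colmap["mod_type"]])
        try:
            pos = int(raw_pos)
        except ValueError:
            n_rejected += 1
            logger.warning("%s: ambiguous/non-integer position %r rejected", path, raw_pos)
            continue
        if mod is None:
            n_rejected += 1
            logger.warning("%s: unknown modification %r rejected", path, row[colmap["mod_type"]])
            continue
        residue = str(row[colmap["residue"]]).strip().upper()
        if not 1 <= pos <= len(database_isoform):
            n_rejected += 1
            logger.warning("%s: position %d outside database isoform", path, pos)
            continue
        db_res = database_isoform.sequence[pos - 1]
        if db_res != residue:
            n_rejected += 1
            logger.warning(
                "%s: residue mismatch at local %d (%s in table, %s in %s)",
                path, pos, residue, db_res, database_isoform.name,
            )
            continue
        try:
            obs = SiteObservation(
                engine=engine,
                sample_id=str(row[colmap["sample_id"]]),
                peptide=str(row[colmap["peptide"]]).strip(),
                local_position=pos,
                mod_type=mod,
                residue=residue,
            )
        except ValueError as exc:
            n_rejected += 1
            logger.warning("%s: rejected row (%s)", path, exc)
            continue
        observations.append(obs)
    return observations, n_rejected


def to_canonical_sites(
    observations: Iterable[SiteObservation],
    database_isoform: TauIsoform,
) -> list[tuple[PtmSite, str, str]]:
    """Map local observations to canonical 2N4R sites.

    Returns ``(site, sample_id, engine)`` triples; unmappable positions are
    rejected with a log line (cannot occur for isoforms that are subsets of
    the canonical sequence, but guards user-supplied coordinate tables).
    """
    out: list[tuple[PtmSite, str, str]] = []
    for obs in observations:
        canonical = database_isoform.canonical_map[obs.local_position - 1]
        if canonical is None:  # defensive: maps are total by construction
            logger.warning("unmappable local position %d", obs.local_position)
            continue
        site = PtmSite(
            canonical_position=canonical,
            residue=obs.residue,
            mod_type=obs.mod_type,
        )
        out.append((site, obs.sample_id, obs.engine))
    return out


def site_frequency(
    canonical_obs: Sequence[tuple[PtmSite, str, str]],
    meta: Mapping[str, SampleMeta],
    grouping: Sequence[str] = ("model", "region", "age"),
) -> PtmSiteMatrix:
    """Site x condition replicate-frequency matrix.

    A condition is the tuple of ``grouping`` metadata fields. Frequency is
    the number of the condition's replicates in which the site was observed
    by *any* engine, divided by the total number of replicates in the
    condition (taken from the metadata, so never-observed samples count in
    the denominator).
    """
    missing = {s for _, s, _ in canonical_obs} - set(meta)
    if missing:
        raise KeyError(f"observations reference samples without metadata: {sorted(missing)}")

    def condition(m: SampleMeta) -> tuple:
        return tuple(getattr(m, g) for g in grouping)

    cond_samples: dict[tuple, set[str]] = {}
    for m in meta.values():
        cond_samples.setdefault(condition(m), set()).add(m.sample_id)
    cond_samples = {c: s for c, s in cond_samples.items() if s}

    # union across engines: set of (site, sample) pairs
    seen: dict[PtmSite, set[str]] = {}
    for site, sample_id, _engine in canonical_obs:
        seen.setdefault(site, set()).add(sample_id)

    conditions = sorted(cond_samples)
    sites = sorted(seen)
    data = {}
    for cond in conditions:
        samples = cond_samples[cond]
        col = [len(seen[site] & samples) / len(samples) for site in sites]
        data["|".join(str(c) for c in cond)] = col
    freq = pd.DataFrame(data, index=[s.display for s in sites], dtype=float)
    return PtmSiteMatrix(frequency=freq, sites={s.display: s for s in sites})


def binary_ptm_matrix(
    matrix: PtmSiteMatrix, threshold: float = 0.5, drop_empty: bool = True
) -> PtmSiteMatrix:
    """Threshold the frequency matrix into binary presence (inclusive >=).

    Rows that are zero across all conditions are dropped by default.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    binary = (matrix.frequency >= threshold).astype(int)
    if drop_empty:
        binary = binary.loc[binary.sum(axis=1) > 0]
    sites = {name: matrix.sites[name] for name in binary.index}
    return PtmSiteMatrix(
        frequency=matrix.frequency.loc[binary.index],
        sites=sites,
        threshold=threshold,
        binary=binary,
    )
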
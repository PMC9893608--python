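"""From transition-level peak areas to peptide ratios, absolute Tau
abundance, and per-peptide modification extent.

The calculus:

* per peptide, ``L/H = sum(light transition areas) / sum(heavy areas)``
  (ratio of sums, robust to low-intensity transitions);
* the heavy-standard concentration is calibrated from the reporter
  (flex-tag) peptide: a known light synthetic spike divided by the reporter
  L/H ratio;
* absolute Tau abundance uses the highest L/H peptide of the sample's
  reference specificity class (shared peptides for mouse samples,
  human-specific for human samples) times the standard concentration,
  scaled by processed volume over tissue mass;
* the unmodified fraction of each peptide is its L/H normalized to the
  highest L/H of its own specificity class in the same sample, clipped to
  [0, 1]; modification extent is one minus that fraction.

Undefined ratios propagate as NaN, never as zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tau_model import Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FLEX_SPIKE",
    "ModExtentMatrix",
    "PeptideQuant",
    "ReadResult",
    "SampleMeta",
    "TransitionRecord",
    "absolute_tau_abundance",
    "build_mod_extent_matrix",
    "peptide_lh_ratio",
    "phosphopeptide_relative_abundance",
    "quantify_sample",
    "read_sample_meta",
    "read_transition_report",
    "standard_concentration_from_flex",
    "unmodified_fraction",
]

#: Default light reporter-peptide spike, fmol/µl.
DEFAULT_FLEX_SPIKE = 15.0

#: Expected number of transitions monitored per precursor.
TRANSITION_BOUNDS = (3, 5)

_REQUIRED_COLUMNS = ("sample_id", "peptide", "label", "transition_id", "area")
_OPTIONAL_COLUMNS = ("retention_time", "modification")


@dataclass(frozen=True)
class TransitionRecord:
    """One monitored precursor->fragment transition's integrated peak area."""

    sample_id: str
    peptide: str
    label: str  # "light" | "heavy"
    transition_id: str
    area: float
    retention_time: float | None = None
    modification: str = ""  # e.g. "phospho" for singly modified light forms

    def __post_init__(self) -> None:
        if self.label not in ("light", "heavy"):
            raise ValueError(f"label must be light|heavy, got {self.label!r}")
        if not (self.area >= 0):
            raise ValueError(f"negative area {self.area}")


@dataclass(frozen=True)
class PeptideQuant:
    """Per-sample, per-peptide light/heavy ratio with transition provenance."""

    sample_id: str
    peptide: Peptide
    lh_ratio: float  # NaN when undefined (no heavy signal)
    n_transitions_light: int
    n_transitions_heavy: int
    flags: tuple[str, ...] = ()

    @property
    def defined(self) -> bool:
        return math.isfinite(self.lh_ratio)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample experimental bookkeeping."""

    sample_id: str
    model: str = "synthetic"  # P301S | P301L | human_P301L | human_control | synthetic
    region: str = "cortex"
    age: float | None = None  # months
    replicate: str = "1"
    tissue_mass: float = 10.0  # mg
    standard_amount: float = 500.0  # fmol heavy full-length standard added
    flex_light_spike: float = DEFAULT_FLEX_SPIKE  # fmol/µl
    processed_volume: float = 50.0  # µl at the point of measurement
    fraction: str = "insoluble"  # insoluble | soluble

    def __post_init__(self) -> None:
        if not self.tissue_mass > 0:
            raise ValueError("tissue_mass must be > 0")
        if not (self.standard_amount > 0 and self.flex_light_spike > 0):
            raise ValueError("spike amounts must be > 0")
        if not self.processed_volume > 0:
            raise ValueError("processed_volume must be > 0")

    @property
    def reference_class(self) -> str:
        """Specificity class used for abundance normalization."""
        return "human_specific" if self.model.startswith("human") else "shared"


@dataclass
class ReadResult:
    records: list[TransitionRecord]
    n_rejected: int = 0


def _read_table(path: Path | str, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_transition_report(
    path: Path | str,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> ReadResult:
    """Read a transition-level peak-area report (CSV/TSV).

    ``column_map`` maps logical column names (``sample_id``, ``peptide``,
    ``label``, ``transition_id``, ``area``, optionally ``retention_time``,
    ``modification``) to the file's actual headers. Rows with negative or
    unparsable areas are rejected and counted; a missing required column is
    a hard error.
    """
    df = _read_table(path, sep)
    colmap = dict(column_map or {})
    rename = {actual: logical for logical, actual in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[TransitionRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            area = float(getattr(row, "area"))
            label = str(getattr(row, "label")).strip().lower()
            rt = getattr(row, "retention_time", None)
            mod = getattr(row, "modification", "")
            if mod is None or (isinstance(mod, float) and math.isnan(mod)) or str(mod) in ("", "nan", "NA"):
                mod = ""
            rec = TransitionRecord(
                sample_id=str(getattr(row, "sample_id")),
                peptide=str(getattr(row, "peptide")).strip(),
                label=label,
                transition_id=str(getattr(row, "transition_id")),
                area=area,
                retention_time=float(rt) if rt not in (None, "", "NA") and rt == rt else None,
                modification=str(mod),
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s: rejected row (%s)", path, exc)
            continue
        records.append(rec)
    if n_rejected:
        logger.info("%s: %d rows rejected", path, n_rejected)
    return ReadResult(records=records, n_rejected=n_rejected)


def read_sample_meta(path: Path | str, sep: str | None = None) -> dict[str, SampleMeta]:
    """Read sample metadata CSV/TSV into a sample_id -> SampleMeta mapping."""
    df = _read_table(path, sep)
    metas: dict[str, SampleMeta] = {}
    for row in df.to_dict(orient="records"):
        kwargs = {}
        for f in (
            "sample_id",
            "model",
            "region",
            "replicate",
            "fraction",
        ):
            if f in row and not pd.isna(row[f]):
                kwargs[f] = str(row[f])
        for f in (
            "age",
            "tissue_mass",
            "standard_amount",
            "flex_light_spike",
            "processed_volume",
        ):
            if f in row and not pd.isna(row[f]) and str(row[f]) != "NA":
                kwargs[f] = float(row[f])
        meta = SampleMeta(**kwargs)
        metas[meta.sample_id] = meta
    return metas


def peptide_lh_ratio(
    records: Sequence[TransitionRecord], peptide: Peptide
) -> PeptideQuant:
    """Aggregate one sample+peptide's transitions into an L/H ratio.

    Ratio of sums: total light area over total heavy area. No heavy signal
    yields an undefined (NaN) ratio with an ``undefined_ratio`` flag; no
    light transitions yield ratio 0 with a ``no_light`` flag.
    """
    recs = [r for r in records if not r.modification]
    samples = {r.sample_id for r in recs}
    peps = {r.peptide for r in recs}
    if len(samples) > 1 or len(peps) > 1:
        raise ValueError(f"records span multiple samples/peptides: {samples}, {peps}")
    light = [r.area for r in recs if r.label == "light"]
    heavy = [r.area for r in recs if r.label == "heavy"]
    flags: list[str] = []
    lo, hi = TRANSITION_BOUNDS
    if heavy and not lo <= len(heavy) <= hi:
        flags.append("transition_count_out_of_bounds")
        logger.warning(
            "%s/%s: %d heavy transitions outside [%d, %d]",
            next(iter(samples), "?"), peptide.sequence, len(heavy), lo, hi,
        )
    if sum(heavy) <= 0:
        flags.append("undefined_ratio")
        lh = float("nan")
    elif not light:
        flags.append("no_light")
        lh = 0.0
    else:
        lh = sum(light) / sum(heavy)
    return PeptideQuant(
        sample_id=next(iter(samples), ""),
        peptide=peptide,
        lh_ratio=lh,
        n_transitions_light=len(light),
        n_transitions_heavy=len(heavy),
        flags=tuple(flags),
    )


def standard_concentration_from_flex(
    flex_quant: PeptideQuant, flex_light_spike: float = DEFAULT_FLEX_SPIKE
) -> float:
    """Heavy-standard concentration (fmol/µl) from the reporter peptide.

    The light reporter is the known synthetic spike; the heavy reporter is
    carried by the full-length standard, so
    ``standard = spike / (L/H of the reporter)``.
    """
    if flex_quant.peptide.specificity != "flex_tag":
        raise ValueError("flex_quant must be a flex_tag peptide")
    lh = flex_quant.lh_ratio
    if not (math.isfinite(lh) and lh > 0):
        raise ValueError(f"reporter L/H ratio must be finite and > 0, got {lh}")
    return flex_light_spike / lh


@dataclass(frozen=True)
class AbundanceResult:
    sample_id: str
    fmol_per_mg: float
    reference_peptide: str
    reference_class: str


def absolute_tau_abundance(
    sample: SampleMeta,
    quants: Sequence[PeptideQuant],
    standard_conc: float,
    processed_volume: float | None = None,
) -> AbundanceResult:
    """Absolute Tau abundance (fmol per mg tissue) for one sample.

    Uses the maximum L/H over the sample's reference specificity class (the
    least-modified peptide reports total Tau), multiplied by the calibrated
    standard concentration and the processed volume, per mg tissue.
    """
    volume = sample.processed_volume if processed_volume is None else processed_volume
    ref_class = sample.reference_class
    candidates = [
        q for q in quants if q.peptide.specificity == ref_class and q.defined
    ]
    if not candidates:
        raise ValueError(
            f"{sample.sample_id}: no quantifiable peptide of reference class "
            f"{ref_class!r}"
        )
    best = max(candidates, key=lambda q: q.lh_ratio)
    fmol_per_mg = best.lh_ratio * standard_conc * volume / sample.tissue_mass
    return AbundanceResult(
        sample_id=sample.sample_id,
        fmol_per_mg=fmol_per_mg,
        reference_peptide=best.peptide.sequence,
        reference_class=ref_class,
    )


def unmodified_fraction(
    quants: Sequence[PeptideQuant],
) -> tuple[dict[str, float], dict[str, str], list[str]]:
    """Per-peptide unmodified fraction for one sample.

    Each peptide's L/H is normalized to the maximum L/H within its own
    specificity class (flex_tag excluded). Values above 1 from measurement
    noise are clipped to 1 with a logged event. Returns
    ``(fractions by peptide sequence, reference peptide by class, events)``.
    """
    events: list[str] = []
    by_class: dict[str, list[PeptideQuant]] = {}
    for q in quants:
        cls = q.peptide.specificity
        if cls in (None, "flex_tag"):
            continue
        by_class.setdefault(cls, []).append(q)
    fractions: dict[str, float] = {}
    references: dict[str, str] = {}
    for cls, qs in by_class.items():
        defined = [q for q in qs if q.defined]
        class_max = max((q.lh_ratio for q in defined), default=float("nan"))
        if not (math.isfinite(class_max) and class_max > 0):
            for q in qs:
                fractions[q.peptide.sequence] = float("nan")
            events.append(f"class_max_undefined:{cls}")
            logger.warning("class %s: reference maximum undefined", cls)
            continue
        ref = max(defined, key=lambda q: q.lh_ratio)
        references[cls] = ref.peptide.sequence
        for q in qs:
            if not q.defined:
                fractions[q.peptide.sequence] = float("nan")
                continue
            frac = q.lh_ratio / class_max
            if frac > 1.0:
                events.append(f"clipped:{q.peptide.sequence}")
                logger.info(
                    "%s/%s: fraction %.4f clipped to 1", q.sample_id,
                    q.peptide.sequence, frac,
                )
                frac = 1.0
            fractions[q.peptide.sequence] = frac
    return fractions, references, events


def phosphopeptide_relative_abundance(
    light_phospho: Sequence[TransitionRecord],
    heavy_counterpart: Sequence[TransitionRecord],
) -> float:
    """Relative amount of a singly modified peptide in one sample.

    The heavy standard is unmodified, so the modified light form is
    referenced to the heavy *unmodified counterpart*:
    ``sum(light modified areas) / sum(heavy counterpart areas)``.
    """
    light = [r.area for r in light_phospho if r.label == "light" and r.modification]
    heavy = [
        r.area for r in heavy_counterpart if r.label == "heavy" and not r.modification
    ]
    if not heavy or sum(heavy) <= 0:
        raise ValueError("missing or zero heavy unmodified counterpart signal")
    return sum(light) / sum(heavy)


@dataclass
class ModExtentMatrix:
    """Peptides x samples matrix of unmodified fractions in [0, 1].

    ``unmodified`` rows are indexed by canonical interval labels ordered
    N- to C-terminally; ``modification_extent`` is its elementwise
    complement. ``reference_peptides`` records, per (sample, class), the
    peptide whose fraction is exactly 1.
    """

    unmodified: pd.DataFrame
    peptides: dict[str, Peptide] = field(default_factory=dict)
    reference_peptides: dict[tuple[str, str], str] = field(default_factory=dict)
    events: list[str] = field(default_factory=list)

    @property
    def modification_extent(self) -> pd.DataFrame:
        return 1.0 - self.unmodified

    def to_tsv(self, path: Path | str, extent: bool = False) -> None:
        df = self.modification_extent if extent else self.unmodified
        df.to_csv(path, sep="\t", index_label="peptide")


@dataclass
class SampleQuantResult:
    sample_id: str
    quants: list[PeptideQuant]
    standard_conc: float
    abundance: AbundanceResult
    fractions: dict[str, float]
    references: dict[str, str]
    events: list[str]


def quantify_sample(
    records: Sequence[TransitionRecord],
    meta: SampleMeta,
    panel: Mapping[str, Peptide],
) -> SampleQuantResult:
    """Run the full per-sample calculus: L/H ratios for every panel peptide,
    reporter calibration, absolute abundance, and unmodified fractions."""
    recs = [r for r in records if r.sample_id == meta.sample_id]
    by_pep: dict[str, list[TransitionRecord]] = {}
    for r in recs:
        if r.peptide in panel and not r.modification:
            by_pep.setdefault(r.peptide, []).append(r)
    quants = [peptide_lh_ratio(rs, panel[seq]) for seq, rs in by_pep.items()]
    flex = [q for q in quants if q.peptide.specificity == "flex_tag"]
    if not flex:
        raise ValueError(f"{meta.sample_id}: no reporter (flex_tag) peptide measured")
    standard_conc = standard_concentration_from_flex(flex[0], meta.flex_light_spike)
    abundance = absolute_tau_abundance(meta, quants, standard_conc)
    fractions, references, events = unmodified_fraction(quants)
    return SampleQuantResult(
        sample_id=meta.sample_id,
        quants=quants,
        standard_conc=standard_conc,
        abundance=abundance,
        fractions=fractions,
        references=references,
        events=events,
    )


def build_mod_extent_matrix(
    results: Iterable[SampleQuantResult], panel: Mapping[str, Peptide]
) -> ModExtentMatrix:
    """Assemble per-sample fractions into the peptides x samples matrix."""
    results = list(results)
    ordered = sorted(
        (p for p in panel.values() if p.specificity != "flex_tag"),
        key=lambda p: (p.start, p.end),
    )
    index = [p.interval for p in ordered]
    data = {}
    refs: dict[tuple[str, str], str] = {}
    events: list[str] = []
    for res in results:
        col = [res.fractions.get(p.sequence, float("nan")) for p in ordered]
        data[res.sample_id] = col
        for cls, seq in res.references.items():
            refs[(res.sample_id, cls)] = seq
        events.extend(f"{res.sample_id}:{e}" for e in res.events)
    df = pd.DataFrame(data, index=index, dtype=float)
    return ModExtentMatrix(
        unmodified=df,
        peptides={p.interval: p for p in ordered},
        reference_peptides=refs,
        events=events,
    )
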
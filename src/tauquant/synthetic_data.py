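"""Ground-truth scenario simulator.

Generates latent truth (per-animal insoluble Tau burden trajectories,
per-peptide modification-extent trajectories coupled to burden, per-site
detection schedules) and emits the pipeline's two input table families:

* transition-level peak-area reports (plus sample metadata), with
  multiplicative lognormal area noise and 3-5 transitions per precursor;
* per-search-engine PTM site tables written in the search database's local
  (0N4R) coordinates, deliberately exercising the canonical mapping path.

A JSON truth sidecar accompanies every emission so that recovery of
abundances and extents can be tested against the latent values. All
randomness flows through a single integer seed; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ptm_consensus import ENGINE_DIALECTS, MOD_RESIDUES, PtmSite
from .srm_quant import DEFAULT_FLEX_SPIKE, SampleMeta
from .tau_model import (
    FLEX_TAG,
    Peptide,
    TauIsoform,
    apply_mutation,
    build_panel,
    load_isoform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingParams",
    "GroundTruthScenario",
    "ModelDesign",
    "NoiseModel",
    "ScenarioConfig",
    "SiteSpec",
    "default_config",
    "emit_engine_site_tables",
    "emit_transition_report",
    "simulate_scenario",
]

#: Engine-specific modification vocabulary used when *writing* site tables.
_ENGINE_MOD_VOCAB: dict[str, dict[str, str]] = {
    "mascot": {
        "phospho": "Phosphorylation",
        "ubiquitin": "Ubiquitination",
        "acetyl": "Acetylation",
        "methyl": "Methylation",
        "citrullination": "Citrullination",
        "oxidation": "Oxidation",
    },
    "maxquant": {
        "phospho": "Phospho (STY)",
        "ubiquitin": "GlyGly (K)",
        "acetyl": "Acetyl (K)",
        "methyl": "Methyl (KR)",
        "citrullination": "Citrullination (R)",
        "oxidation": "Oxidation (M)",
    },
}


@dataclass(frozen=True)
class ModelDesign:
    """Condition grid and burden trajectory for one animal model."""

    name: str
    mutation: str | None
    timepoints: tuple[float, ...]
    regions: tuple[str, ...]
    n_replicates: int = 6
    onset_time: float = 4.0
    burden_baseline: float = 5.0  # fmol/mg before onset
    burden_plateau: float = 250.0  # fmol/mg late-stage (region-scaled)
    burden_rate: float = 2.0  # logistic steepness per month
    region_scale: Mapping[str, float] = field(
        default_factory=lambda: {"cortex": 1.0}
    )
    region_delay: Mapping[str, float] = field(default_factory=dict)
    animal_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or not self.timepoints or not self.regions:
            raise ValueError(f"model {self.name}: invalid condition grid")
        if self.animal_cv < 0:
            raise ValueError("animal_cv must be >= 0")
        if min(self.burden_baseline, self.burden_plateau) <= 0:
            raise ValueError("burden levels must be > 0")

    def burden_mean(self, region: str, t: float) -> float:
        """Latent mean insoluble Tau (fmol/mg) at time t in a region."""
        scale = self.region_scale.get(region, 1.0)
        delay = self.region_delay.get(region, 0.0)
        lo = self.burden_baseline
        hi = self.burden_plateau * scale
        z = self.burden_rate * (t - (self.onset_time + delay))
        return lo + (hi - lo) / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class CouplingParams:
    """Sigmoid coupling of a peptide's true modification extent to burden:
    ``extent = max_extent / (1 + exp(-slope * (log10 burden - half)))``."""

    max_extent: float = 0.85
    half_log10: float = 1.7
    slope: float = 2.5

    def extent(self, burden: float) -> float:
        if burden <= 0:
            return 0.0
        z = self.slope * (np.log10(burden) - self.half_log10)
        return float(self.max_extent / (1.0 + np.exp(-z)))


@dataclass(frozen=True)
class SiteSpec:
    """Planted detection schedule for one PTM site.

    Detection probability is ``p_after`` from ``first_time`` onward
    (``first_time=None`` means always detectable) and ``p_before`` earlier.
    """

    canonical_position: int
    residue: str
    mod_type: str
    first_time: float | None = None
    p_before: float = 0.0
    p_after: float = 1.0

    def __post_init__(self) -> None:
        if self.residue not in MOD_RESIDUES[self.mod_type]:
            raise ValueError(f"{self.mod_type} not allowed on {self.residue}")
        for p in (self.p_before, self.p_after):
            if not 0 <= p <= 1:
                raise ValueError("detection probabilities must be in [0, 1]")

    def probability(self, t: float) -> float:
        if self.first_time is None or t >= self.first_time:
            return self.p_after
        return self.p_before

    @property
    def site(self) -> PtmSite:
        return PtmSite(
            canonical_position=self.canonical_position,
            residue=self.residue,
            mod_type=self.mod_type,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal area noise with unit mean, plus the
    transition-count range and optional per-peptide response factors."""

    area_cv: float = 0.10
    transition_count: tuple[int, int] = (3, 5)
    response_factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.area_cv < 0:
            raise ValueError("area_cv must be >= 0")
        lo, hi = self.transition_count
        if not (1 <= lo <= hi):
            raise ValueError("invalid transition_count range")
        if any(v <= 0 for v in self.response_factors.values()):
            raise ValueError("response factors must be > 0")

    def factors(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Unit-mean lognormal noise factors; exactly 1.0 when cv = 0."""
        if self.area_cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(self.area_cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


#: Peptide intervals whose modification extent is coupled to burden by
#: default (the PRD / C-terminal drivers).
DRIVER_INTERVALS = ("195-209", "212-221", "386-395", "396-406")


def _default_models() -> tuple[ModelDesign, ...]:
    return (
        ModelDesign(
            name="P301S",
            mutation="P301S",
            timepoints=(2.0, 3.0, 4.0, 5.0),
            regions=("cortex", "brainstem", "subcortical"),
            n_replicates=6,
            onset_time=4.0,
            burden_plateau=250.0,
            region_scale={"cortex": 1.0, "brainstem": 1.4, "subcortical": 0.4},
            region_delay={"brainstem": -0.5, "subcortical": 0.5},
        ),
        ModelDesign(
            name="P301L",
            mutation="P301L",
            timepoints=(1.5, 2.5, 4.0, 6.0, 8.0),
            regions=("cortex", "hippocampus", "subcortical"),
            n_replicates=6,
            onset_time=4.0,
            burden_plateau=1000.0,
            region_scale={"cortex": 1.0, "hippocampus": 1.0, "subcortical": 0.3},
            region_delay={"subcortical": 2.0},
        ),
    )


def _default_sites() -> tuple[SiteSpec, ...]:
    return (
        SiteSpec(199, "S", "phospho", first_time=None),
        SiteSpec(404, "S", "phospho", first_time=None),
        SiteSpec(181, "T", "phospho", first_time=None),
        SiteSpec(202, "S", "phospho", first_time=2.5),
        SiteSpec(212, "T", "phospho", first_time=4.0),
        SiteSpec(214, "S", "phospho", first_time=4.0),
        SiteSpec(217, "T", "phospho", first_time=4.0),
        SiteSpec(396, "S", "phospho", first_time=4.0),
        SiteSpec(403, "T", "phospho", first_time=5.0),
        SiteSpec(155, "R", "citrullination", first_time=2.5),
        SiteSpec(259, "K", "ubiquitin", first_time=6.0),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic study."""

    models: tuple[ModelDesign, ...] = field(default_factory=_default_models)
    coupling: Mapping[str, CouplingParams] = field(
        default_factory=lambda: {iv: CouplingParams() for iv in DRIVER_INTERVALS}
    )
    constant_extents: Mapping[str, float] = field(default_factory=dict)
    sites: tuple[SiteSpec, ...] = field(default_factory=_default_sites)
    engines: tuple[str, ...] = ("mascot", "maxquant", "proteinpilot")
    engine_sensitivity: Mapping[str, float] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    tissue_mass: float = 10.0  # mg
    standard_amount: float = 500.0  # fmol heavy standard per sample
    flex_light_spike: float = DEFAULT_FLEX_SPIKE  # fmol/µl
    processed_volume: float = 50.0  # µl
    endogenous_mouse_ratio: float = 0.0  # extra light signal on shared peptides
    phospho_share: float = 0.5  # fraction of extent carried by the single-phospho form
    emit_phospho: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for ext in self.constant_extents.values():
            if not 0 <= ext <= 1:
                raise ValueError("constant extents must be in [0, 1]")
        if self.endogenous_mouse_ratio < 0:
            raise ValueError("endogenous_mouse_ratio must be >= 0")
        for m in self.models:
            if m.n_replicates < 1 or not m.timepoints:
                raise ValueError(f"model {m.name}: invalid grid")


def default_config(**overrides) -> ScenarioConfig:
    return dataclasses.replace(ScenarioConfig(), **overrides)


@dataclass
class GroundTruthScenario:
    """Materialized latent truth for one simulated study."""

    config: ScenarioConfig
    samples: list[SampleMeta]
    burden: dict[str, float]  # sample_id -> insoluble Tau fmol/mg (truth)
    extent: pd.DataFrame  # interval x sample_id true modification extent
    site_probs: pd.DataFrame  # site display x sample_id detection probability
    panels: dict[str, dict[str, Peptide]]  # model name -> sequence -> Peptide
    model_of: dict[str, str]  # sample_id -> model name
    seed: int

    def unmodified(self) -> pd.DataFrame:
        return 1.0 - self.extent

    def meta_by_sample(self) -> dict[str, SampleMeta]:
        return {m.sample_id: m for m in self.samples}


def _intervals(panel: Mapping[str, Peptide]) -> dict[str, Peptide]:
    return {
        p.interval: p for p in panel.values() if p.specificity != "flex_tag"
    }


def simulate_scenario(
    config: ScenarioConfig | None = None, seed: int | None = None
) -> GroundTruthScenario:
    """Materialize the latent truth for a scenario configuration."""
    config = config or ScenarioConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    panels = {m.name: build_panel(m.mutation) for m in config.models}

    samples: list[SampleMeta] = []
    burden: dict[str, float] = {}
    model_of: dict[str, str] = {}
    extent_cols: dict[str, pd.Series] = {}
    prob_cols: dict[str, pd.Series] = {}
    site_index = [s.site.display for s in config.sites]

    for model in config.models:
        intervals = _intervals(panels[model.name])
        for region in model.regions:
            for t in model.timepoints:
                for rep in range(1, model.n_replicates + 1):
                    sid = f"{model.name}_{region}_{t:g}m_r{rep}"
                    mean_b = model.burden_mean(region, t)
                    if model.animal_cv > 0:
                        sigma = np.sqrt(np.log1p(model.animal_cv**2))
                        b = float(
                            mean_b
                            * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                        )
                    else:
                        b = float(mean_b)
                    samples.append(
                        SampleMeta(
                            sample_id=sid,
                            model=model.name,
                            region=region,
                            age=t,
                            replicate=str(rep),
                            tissue_mass=config.tissue_mass,
                            standard_amount=config.standard_amount,
                            flex_light_spike=config.flex_light_spike,
                            processed_volume=config.processed_volume,
                        )
                    )
                    burden[sid] = b
                    model_of[sid] = model.name
                    ext = {}
                    for interval in intervals:
                        if interval in config.constant_extents:
                            ext[interval] = config.constant_extents[interval]
                        elif interval in config.coupling:
                            ext[interval] = config.coupling[interval].extent(b)
                        else:
                            ext[interval] = 0.0
                    extent_cols[sid] = pd.Series(ext)
                    prob_cols[sid] = pd.Series(
                        {s.site.display: s.probability(t) for s in config.sites},
                    )

    extent = pd.DataFrame(extent_cols)
    extent = extent.loc[sorted(extent.index, key=_interval_key)]
    probs = pd.DataFrame(prob_cols).reindex(site_index)
    return GroundTruthScenario(
        config=config,
        samples=samples,
        burden=burden,
        extent=extent,
        site_probs=probs,
        panels=panels,
        model_of=model_of,
        seed=seed,
    )


def _interval_key(interval: str) -> tuple[int, int]:
    a, b = interval.split("-")
    return int(a), int(b)


def _transition_shares(n: int) -> np.ndarray:
    shares = np.arange(1, n + 1, dtype=float)
    return shares / shares.sum()


def emit_transition_report(
    truth: GroundTruthScenario,
    noise: NoiseModel | None = None,
    seed: int | None = None,
    out_dir: Path | str = ".",
) -> dict[str, Path]:
    """Write transitions.csv, samples.csv and a truth.json sidecar.

    Heavy areas are proportional to the standard concentration and the
    peptide's response factor; light areas additionally carry the true
    unmodified fraction and the endogenous/standard abundance ratio. With
    ``area_cv = 0`` the pipeline recovers the truth exactly.
    """
    noise = noise if noise is not None else truth.config.noise
    seed = truth.seed + 1 if seed is None else seed
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = truth.config

    # stable per-peptide structure: response factor and transition count
    all_seqs = sorted({seq for panel in truth.panels.values() for seq in panel})
    lo, hi = noise.transition_count
    structure: dict[str, tuple[float, int]] = {}
    for seq in all_seqs:
        rf = noise.response_factors.get(seq)
        if rf is None:
            rf = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
        n_t = int(rng.integers(lo, hi + 1))
        structure[seq] = (rf, n_t)

    rows: list[dict] = []
    phospho_truth: dict[str, dict[str, float]] = {}
    for meta in truth.samples:
        sid = meta.sample_id
        panel = truth.panels[truth.model_of[sid]]
        intervals = _intervals(panel)
        std_conc = meta.standard_amount / meta.processed_volume
        endo_conc = truth.burden[sid] * meta.tissue_mass / meta.processed_volume
        unmod = truth.unmodified()[sid]
        for seq, pep in sorted(panel.items()):
            rf, n_t = structure[seq]
            shares = _transition_shares(n_t)
            if pep.specificity == "flex_tag":
                light_level = rf * meta.flex_light_spike
                heavy_level = rf * std_conc
            else:
                u = float(unmod[pep.interval])
                endo = endo_conc
                if pep.specificity == "shared" and cfg.endogenous_mouse_ratio > 0:
                    endo = endo_conc * (1.0 + cfg.endogenous_mouse_ratio)
                light_level = rf * endo * u
                heavy_level = rf * std_conc
            lf = noise.factors(rng, n_t)
            hf = noise.factors(rng, n_t)
            for k in range(n_t):
                rows.append(
                    dict(
                        sample_id=sid,
                        peptide=seq,
                        label="light",
                        transition_id=f"y{k + 3}",
                        area=light_level * shares[k] * lf[k],
                        modification="",
                    )
                )
                rows.append(
                    dict(
                        sample_id=sid,
                        peptide=seq,
                        label="heavy",
                        transition_id=f"y{k + 3}",
                        area=heavy_level * shares[k] * hf[k],
                        modification="",
                    )
                )
            if (
                cfg.emit_phospho
                and pep.specificity != "flex_tag"
                and pep.interval in cfg.coupling
            ):
                stoich = (1.0 - float(unmod[pep.interval])) * cfg.phospho_share
                pf = noise.factors(rng, n_t)
                for k in range(n_t):
                    rows.append(
                        dict(
                            sample_id=sid,
                            peptide=seq,
                            label="light",
                            transition_id=f"y{k + 3}p",
                            area=rf * endo_conc * stoich * shares[k] * pf[k],
                            modification="phospho",
                        )
                    )
                phospho_truth.setdefault(sid, {})[pep.interval] = (
                    endo_conc * stoich / std_conc
                )

    transitions = pd.DataFrame(rows)
    transitions_path = out / "transitions.csv"
    transitions.to_csv(transitions_path, index=False)

    meta_df = pd.DataFrame([dataclasses.asdict(m) for m in truth.samples])
    meta_df["model_mutation"] = [
        next(m.mutation for m in cfg.models if m.name == truth.model_of[s])
        for s in meta_df["sample_id"]
    ]
    samples_path = out / "samples.csv"
    meta_df.to_csv(samples_path, index=False)

    sidecar = {
        "seed": seed,
        "burden_fmol_per_mg": truth.burden,
        "extent": {
            sid: truth.extent[sid].to_dict() for sid in truth.extent.columns
        },
        "phospho_relative": phospho_truth,
        "site_probability": {
            sid: truth.site_probs[sid].to_dict() for sid in truth.site_probs.columns
        },
        "onset_time": {m.name: m.onset_time for m in cfg.models},
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return {
        "transitions": transitions_path,
        "samples": samples_path,
        "truth": truth_path,
    }


def emit_engine_site_tables(
    truth: GroundTruthScenario,
    engines: Sequence[str] | None = None,
    seed: int | None = None,
    out_dir: Path | str = ".",
) -> dict[str, Path]:
    """Write per-engine PTM site tables in 0N4R-local coordinates.

    Each engine draws independent Bernoulli detections from the planted
    per-sample probabilities (scaled by the engine's sensitivity); positions
    are converted from canonical numbering to the search database's local
    coordinates to exercise the consensus module's mapping path.
    """
    cfg = truth.config
    engines = tuple(engines) if engines is not None else cfg.engines
    seed = truth.seed + 2 if seed is None else seed
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    db_isoforms: dict[str, TauIsoform] = {}
    db_peptides: dict[str, dict[int, str]] = {}
    for model in cfg.models:
        iso = load_isoform("0N4R")
        if model.mutation:
            iso = apply_mutation(iso, model.mutation)
        db_isoforms[model.name] = iso
        # covering 0-missed tryptic peptide per local position
        from .tau_model import digest  # local import avoids cycle at module load

        cover: dict[int, str] = {}
        pos = 1
        for pep in digest(iso):
            for _ in pep.sequence:
                cover[pos] = pep.sequence
                pos += 1
        db_peptides[model.name] = cover

    paths: dict[str, Path] = {}
    for engine in engines:
        dialect = ENGINE_DIALECTS[engine]
        sens = cfg.engine_sensitivity.get(engine, 1.0)
        vocab = _ENGINE_MOD_VOCAB.get(engine, {})
        rows = []
        for meta in truth.samples:
            sid = meta.sample_id
            iso = db_isoforms[truth.model_of[sid]]
            for spec in cfg.sites:
                local = iso.local_position(spec.canonical_position)
                if local is None:
                    continue  # site falls in a region absent from the database isoform
                p = min(1.0, truth.site_probs.at[spec.site.display, sid] * sens)
                if rng.random() >= p:
                    continue
                rows.append(
                    {
                        dialect["sample_id"]: sid,
                        dialect["peptide"]: db_peptides[truth.model_of[sid]].get(
                            local, ""
                        ),
                        dialect["position"]: local,
                        dialect["residue"]: spec.residue,
                        dialect["mod_type"]: vocab.get(spec.mod_type, spec.mod_type),
                    }
                )
        df = pd.DataFrame(
            rows,
            columns=[
                dialect["sample_id"],
                dialect["peptide"],
                dialect["position"],
                dialect["residue"],
                dialect["mod_type"],
            ],
        )
        path = out / f"sites_{engine}.csv"
        df.to_csv(path, index=False)
        paths[engine] = path
    return paths
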
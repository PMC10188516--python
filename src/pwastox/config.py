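"""Simulation and pipeline configuration objects.

A :class:`SimConfig` fully parameterizes the synthetic study: the agricultural
landscape, the application records, the case-control cohort with its causal
structure, the high-content screen plates, and the mito-stress traces.  All
randomness flows from ``seed`` through named per-artifact streams so that
regenerating one artifact never perturbs the others.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

ACRE_M2 = 4046.8564224  # square meters per acre

# fixed stream labels: one independent generator per simulated artifact
_STREAMS = {"landscape": 1, "applications": 2, "cohort": 3, "plate": 4, "ocr": 5,
            "exposure": 6, "combo": 7}


@dataclass(frozen=True)
class PesticideSpec:
    """One active ingredient with its group annotations.

    ``crop`` restricts applications to parcels growing that crop (e.g. the
    simulated defoliants, which in the field are applied almost exclusively
    on cotton).
    """

    pid: str
    use_type: str = "insecticide"
    chemical_class: str = "organophosphorus"
    toxicity: tuple[str, ...] = ()
    crop: str | None = None


@dataclass(frozen=True)
class CoappCluster:
    """A co-use group: members are applied to the same parcel-years with
    probability ``correlation`` (1.0 means identical application sets)."""

    members: tuple[str, ...]
    correlation: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError("co-application correlation must lie in [0, 1]")


@dataclass(frozen=True)
class WaveSpec:
    name: str
    n_cases: int
    n_controls: int
    index_years: tuple[int, int]  # inclusive range of index years

    def __post_init__(self):
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("wave counts must be non-negative")


@dataclass(frozen=True)
class HillParams:
    """Four-parameter Hill dose-response for well counts (decreasing in dose)."""

    top: float
    bottom: float
    ec50: float
    slope: float = 1.0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be > 0")

    def response(self, dose: float) -> float:
        if dose < 0:
            raise ValueError("dose must be non-negative")
        if dose == 0:
            return self.top
        return self.bottom + (self.top - self.bottom) / (1.0 + (dose / self.ec50) ** self.slope)


@dataclass(frozen=True)
class OcrTruth:
    """True mito-stress levels (protein-normalized OCR units)."""

    non_mito: float = 10.0
    basal: float = 90.0       # above non-mito
    atp_linked: float = 60.0  # drop after oligomycin
    maximal: float = 140.0    # above non-mito, after FCCP
    noise_sd: float = 0.0


@dataclass
class SimConfig:
    # landscape
    n_parcels: int = 144
    region_extent: tuple[float, float] = (12000.0, 12000.0)  # meters
    crops: tuple[str, ...] = ("cotton", "grape", "citrus", "almond")
    crop_weights: tuple[float, ...] = (0.3, 0.3, 0.2, 0.2)
    # pesticides and application process
    pesticides: list[PesticideSpec] = field(default_factory=list)
    coapplication_clusters: list[CoappCluster] = field(default_factory=list)
    years: tuple[int, int] = (1974, 2005)
    app_prob: float = 0.25           # P(a pesticide is applied to an eligible parcel-year)
    log_pounds_mean: float = 3.0     # lognormal pounds per application
    log_pounds_sd: float = 0.8
    # cohort
    waves: list[WaveSpec] = field(default_factory=lambda: [
        WaveSpec("wave1", 100, 100, (2000, 2007)),
        WaveSpec("wave2", 100, 100, (2009, 2015)),
    ])
    causal_effects: dict[str, float] = field(default_factory=dict)     # pid -> log-OR per SD
    covariate_effects: dict[str, float] = field(default_factory=dict)  # covariate -> log-OR
    workplace_prob: float = 0.6      # P(participant has any workplace history)
    # statistical exposure model (cohort-level fast route)
    exposure_prevalence: float = 0.4
    log_intensity_mean: float = 1.0
    log_intensity_sd: float = 1.0
    # screen
    plate_truth: dict[str, HillParams] = field(default_factory=dict)
    interaction_multipliers: dict[frozenset, float] = field(default_factory=dict)
    doses: tuple[float, ...] = (1.1, 3.3, 10.0, 30.0)
    n_replicates: int = 3
    n_dmso_wells: int = 8
    n_positive_wells: int = 6
    well_noise_sd: float = 0.08      # lognormal sigma on well counts
    # the dim background population dominates, so the control-referenced
    # mean + 3 SD intensity cutoff lands between the two populations
    dim_per_well: int = 1500         # background (debris) objects per well
    dim_intensity: tuple[float, float] = (700.0, 60.0)     # mean, sd
    bright_intensity: tuple[float, float] = (30000.0, 2000.0)
    # OCR
    ocr_truth: OcrTruth = field(default_factory=OcrTruth)
    n_ocr_traces: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_parcels <= 0:
            raise ValueError("n_parcels must be > 0")
        if self.region_extent[0] <= 0 or self.region_extent[1] <= 0:
            raise ValueError("region extent must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")
        known = {p.pid for p in self.pesticides}
        for cl in self.coapplication_clusters:
            missing = set(cl.members) - known
            if missing:
                raise ValueError(f"cluster members not in pesticide list: {sorted(missing)}")
        for pid in self.causal_effects:
            if pid not in known:
                raise ValueError(f"causal effect given for unknown pesticide {pid!r}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for one artifact, derived from the master seed."""
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])

    @property
    def pesticide_ids(self) -> list[str]:
        return [p.pid for p in self.pesticides]

    def cluster_of(self, pid: str) -> int | None:
        for i, cl in enumerate(self.coapplication_clusters):
            if pid in cl.members:
                return i
        return None


def default_pesticides(n: int = 20) -> tuple[list[PesticideSpec], list[CoappCluster]]:
    """A demo panel: a six-member cotton cluster (defoliants plus a
    dinitroaniline herbicide, all restricted to cotton), a cluster of
    cholinesterase-inhibiting insecticides, and independent singletons."""
    pest = []
    cotton = []
    for i in range(5):
        pid = f"defoliant_{i:02d}"
        pest.append(PesticideSpec(pid, use_type="defoliant",
                                  chemical_class="organophosphorus",
                                  toxicity=("cholinesterase_inhibitor",) if i < 3 else (),
                                  crop="cotton"))
        cotton.append(pid)
    pest.append(PesticideSpec("herbicide_cotton", use_type="herbicide",
                              chemical_class="dinitroaniline", crop="cotton"))
    cotton.append("herbicide_cotton")
    chl = []
    for i in range(5):
        pid = f"insecticide_{i:02d}"
        pest.append(PesticideSpec(pid, use_type="insecticide",
                                  chemical_class="carbamate",
                                  toxicity=("cholinesterase_inhibitor", "acute_toxicity")))
        chl.append(pid)
    for i in range(max(n - 11, 0)):
        pest.append(PesticideSpec(f"herbicide_{i:02d}", use_type="herbicide",
                                  chemical_class="triazine", toxicity=()))
    clusters = [CoappCluster(tuple(cotton), 0.8), CoappCluster(tuple(chl), 0.8)]
    return pest, clusters


def default_plate_truth(n_compounds: int = 39, n_toxic: int = 10):
    """Hill truth for the demo screen: ``n_toxic`` compounds kill cells with
    EC50 near 10 uM; the rest are flat."""
    truth = {}
    toxic = []
    for i in range(n_compounds):
        name = f"compound_{i:02d}"
        if i < n_toxic:
            truth[name] = HillParams(top=100.0, bottom=8.0, ec50=8.0 + i, slope=2.0)
            toxic.append(name)
        else:
            truth[name] = HillParams(top=100.0, bottom=100.0, ec50=10.0, slope=1.0)
    return truth, toxic


def default_config(seed: int = 0, n_pesticides: int = 20) -> SimConfig:
    """Demo study: the screen compounds are the pesticide panel itself, six of
    which are truly mDA-toxic, with one synergistic cotton-cluster pair."""
    pest, clusters = default_pesticides(n_pesticides)
    cfg = SimConfig(pesticides=pest, coapplication_clusters=clusters, seed=seed)
    toxic = ["herbicide_cotton", "defoliant_00", "insecticide_00",
             "insecticide_01", "herbicide_00", "herbicide_01"]
    truth = {}
    for i, p in enumerate(cfg.pesticide_ids):
        if p in toxic:
            truth[p] = HillParams(top=100.0, bottom=8.0, ec50=8.0 + i, slope=2.0)
        else:
            truth[p] = HillParams(top=100.0, bottom=100.0, ec50=10.0, slope=1.0)
    cfg.plate_truth = truth
    cfg.causal_effects = {"defoliant_00": float(np.log(1.5)),
                          "insecticide_00": float(np.log(1.6)),
                          "herbicide_cotton": float(np.log(1.5))}
    cfg.interaction_multipliers = {
        frozenset({"herbicide_cotton", "defoliant_00"}): 0.5}
    return cfg


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from a YAML mapping of field overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(seed=int(raw.pop("seed", 0)),
                         n_pesticides=int(raw.pop("n_pesticides", 20)))
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown SimConfig field {key!r}")
        if key == "waves":
            val = [WaveSpec(**w) for w in val]
        setattr(cfg, key, val)
    return cfg


def config_digest(cfg: SimConfig) -> str:
    """Stable short hash of a configuration, for run manifests."""
    import hashlib
    import json

    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            o = dataclasses.asdict(o)
        if isinstance(o, dict):
            return {("|".join(sorted(k)) if isinstance(k, frozenset) else str(k)): norm(v)
                    for k, v in o.items()}
        if isinstance(o, (list, tuple, set, frozenset)):
            return [norm(v) for v in o]
        if isinstance(o, (str, int, float, bool)) or o is None:
            return o
        return str(o)

    payload = json.dumps(norm(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
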
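"""Synthetic ground-truth data generator.

Builds genomes, clone copy-number profiles on a small clone tree, overdispersed
single-cell bin depths with tunable MAPD, bulk regions as clone mixtures with
diploid contamination, dual-caller mutation tables with false negatives, and
single-cell validation assays with allelic dropout. Every output is paired with
its truth table so downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .grid import BinGrid
from .profiles import PHI_INV_75

__all__ = [
    "CNEvent",
    "MutationSpec",
    "SimConfig",
    "SimTruth",
    "build_genome",
    "plant_events",
    "assign_cells",
    "simulate_truth",
    "simulate_cell_depths",
    "simulate_region_depths",
    "simulate_mutation_calls",
]

DIPLOID = "diploid"
LN2 = np.log(2.0)


@dataclass(frozen=True)
class CNEvent:
    """One integer copy-number event owned by a clone."""

    clone: str
    chrom: str
    start: int
    end: int
    cn: int


@dataclass(frozen=True)
class MutationSpec:
    """One planted variant: coordinates, carrier clones, assay panel membership."""

    name: str
    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: str
    carriers: tuple = ()
    gene: str = ""
    effect: str = "nonsynonymous"
    base_quality: float = 60.0
    is_indel: bool = False
    germline: bool = False


@dataclass
class SimConfig:
    genome_spec: list = field(default_factory=lambda: [("chr1", 60_000_000)])
    bin_size: int = 500_000
    clone_tree: dict = field(default_factory=lambda: {"founder": None})
    event_list: list = field(default_factory=list)  # CNEvent or 5-tuples
    clone_fractions_per_region: dict = field(
        default_factory=lambda: {"A": {"founder": 1.0}}
    )
    diploid_contamination: dict | float = 0.0  # per region or scalar
    depth_mean: float = 60.0  # reads per full-width bin for CN=2
    depth_dispersion: float = 0.0  # NB overdispersion floor (var = m + a*m^2)
    target_mapd: float | None = 0.20  # calibrates dispersion when set
    wave_sd: float = 0.05  # cell-specific lognormal wave amplitude
    wave_period_bins: int = 200
    n_cells_per_region: dict | int = 10
    mutation_spec: list = field(default_factory=list)
    vaf_noise_sd: float = 0.0
    caller_fn_rate: float = 0.0
    ado_rate: float = 0.0
    assay_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.event_list = [e if isinstance(e, CNEvent) else CNEvent(*e) for e in self.event_list]
        lengths = dict(self.genome_spec)
        for e in self.event_list:
            if e.clone not in self.clone_tree:
                raise ValueError(f"event references unknown clone {e.clone!r}")
            if e.chrom not in lengths:
                raise ValueError(f"event references unknown chromosome {e.chrom!r}")
            if not (0 <= e.start < e.end <= lengths[e.chrom]):
                raise ValueError(f"event {e} outside chromosome bounds")
            if e.cn < 0:
                raise ValueError("event CN must be >= 0")
        for region, fr in self.clone_fractions_per_region.items():
            total = sum(fr.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"clone fractions in region {region!r} sum to {total}, not 1")
            for clone in fr:
                if clone not in self.clone_tree:
                    raise ValueError(f"region {region!r} references unknown clone {clone!r}")
        for name, rate in [
            ("caller_fn_rate", self.caller_fn_rate),
            ("ado_rate", self.ado_rate),
            ("assay_fail_rate", self.assay_fail_rate),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        contam = self.contamination_map()
        if any(not 0.0 <= d <= 1.0 for d in contam.values()):
            raise ValueError("diploid_contamination must be in [0, 1]")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if self.target_mapd is not None and self.target_mapd <= 0:
            raise ValueError("target_mapd must be > 0")

    @property
    def regions(self) -> list:
        return list(self.clone_fractions_per_region)

    def contamination_map(self) -> dict:
        if isinstance(self.diploid_contamination, dict):
            return {r: self.diploid_contamination.get(r, 0.0) for r in self.regions}
        return {r: float(self.diploid_contamination) for r in self.regions}

    def cells_per_region(self) -> dict:
        if isinstance(self.n_cells_per_region, dict):
            return dict(self.n_cells_per_region)
        return {r: int(self.n_cells_per_region) for r in self.regions}

    def to_yaml(self, path) -> None:
        data = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("event_list", "mutation_spec")
        }
        data["event_list"] = [list(e.__dict__.values()) for e in self.event_list]
        data["mutation_spec"] = [m.__dict__ for m in self.mutation_spec]
        data["genome_spec"] = [list(g) for g in self.genome_spec]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["genome_spec"] = [tuple(g) for g in data.get("genome_spec", [])]
        data["mutation_spec"] = [
            MutationSpec(**{**m, "carriers": tuple(m.get("carriers", ()))})
            for m in data.get("mutation_spec", [])
        ]
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    grid: BinGrid
    clone_profiles: dict  # clone -> int array over bins (includes "diploid")
    cell_assignments: dict  # cell -> clone name
    cell_regions: dict  # cell -> region name
    region_compositions: dict  # region -> {clone: fraction incl. diploid}
    mutation_truth: pd.DataFrame | None = None  # variant x cell bool

    @property
    def cells(self) -> list:
        return list(self.cell_assignments)


def build_genome(config: SimConfig) -> BinGrid:
    """Tile the configured genome into fixed-width bins (last bin may be short)."""
    return BinGrid.tile(config.genome_spec, config.bin_size)


def _tree_order(tree: dict) -> list:
    """Clones in parent-before-child order; validates the parent map."""
    order, seen = [], set()

    def visit(clone, trail=()):
        if clone in trail:
            raise ValueError(f"clone tree has a cycle at {clone!r}")
        if clone in seen or clone is None:
            return
        parent = tree[clone]
        if parent is not None:
            if parent not in tree:
                raise ValueError(f"clone {clone!r} has unknown parent {parent!r}")
            visit(parent, trail + (clone,))
        seen.add(clone)
        order.append(clone)

    for clone in tree:
        visit(clone)
    return order


def plant_events(grid: BinGrid, config: SimConfig) -> dict:
    """Realize per-clone integer CN profiles along the clone tree.

    Children inherit the parent profile, then apply their own events. A bin
    takes an event's CN iff the event covers >= 50% of the bin width. Two
    events of one clone claiming the same bin with different CN is an error.
    """
    order = _tree_order(config.clone_tree)
    n = len(grid)
    own: dict = {c: {} for c in order}  # clone -> {bin: cn}
    for e in config.event_list:
        sel = grid.chrom == e.chrom
        overlap = np.minimum(grid.end, e.end) - np.maximum(grid.start, e.start)
        hit = np.flatnonzero(sel & (overlap >= 0.5 * grid.widths))
        for b in hit:
            prev = own[e.clone].get(b)
            if prev is not None and prev != e.cn:
                raise ValueError(f"conflicting events for clone {e.clone!r} at bin {b}")
            own[e.clone][int(b)] = e.cn
    profiles = {DIPLOID: np.full(n, 2, dtype=np.int64)}
    for clone in order:
        parent = config.clone_tree[clone]
        base = profiles[parent] if parent is not None else profiles[DIPLOID]
        prof = base.copy()
        for b, cn in own[clone].items():
            prof[b] = cn
        profiles[clone] = prof
    return profiles


def assign_cells(config: SimConfig, rng: np.random.Generator) -> tuple[dict, dict]:
    """Draw a clone (or diploid contaminant) for every sorted cell."""
    assignments, regions = {}, {}
    contam = config.contamination_map()
    for region, n in config.cells_per_region().items():
        fr = config.clone_fractions_per_region[region]
        clones = list(fr) + [DIPLOID]
        p = np.array([fr[c] * (1 - contam[region]) for c in fr] + [contam[region]])
        picks = rng.choice(len(clones), size=n, p=p / p.sum())
        for i, k in enumerate(picks):
            cell = f"{region}{i + 1}"
            assignments[cell] = clones[k]
            regions[cell] = region
    return assignments, regions


def simulate_truth(config: SimConfig) -> SimTruth:
    """Build the full ground-truth object (grid, clone profiles, cell draws)."""
    grid = build_genome(config)
    profiles = plant_events(grid, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    assignments, cell_regions = assign_cells(config, rng)
    contam = config.contamination_map()
    comps = {}
    for region, fr in config.clone_fractions_per_region.items():
        d = contam[region]
        comp = {c: f * (1 - d) for c, f in fr.items()}
        comp[DIPLOID] = comp.get(DIPLOID, 0.0) + d
        comps[region] = comp
    truth = SimTruth(grid, profiles, assignments, cell_regions, comps)
    truth.mutation_truth = _mutation_truth(truth, config)
    return truth


def _mutation_truth(truth: SimTruth, config: SimConfig) -> pd.DataFrame | None:
    if not config.mutation_spec:
        return None
    cells = truth.cells
    rows = {}
    for m in config.mutation_spec:
        if m.germline:
            rows[m.name] = [True] * len(cells)
            continue
        if not m.carriers:
            raise ValueError(f"variant {m.name!r} assigned to no clone")
        carriers = set(m.carriers)
        rows[m.name] = [truth.cell_assignments[c] in carriers for c in cells]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cells)


def _calibrated_dispersion(config: SimConfig) -> float:
    """NB overdispersion so realized log2-ratio MAPD ~= target_mapd."""
    if config.target_mapd is None:
        return config.depth_dispersion
    sigma_log2 = config.target_mapd / (np.sqrt(2.0) * PHI_INV_75)
    var_ln = (sigma_log2 * LN2) ** 2
    # var(log count) ~= 1/mean + alpha for NB(mean, var = mean + alpha*mean^2)
    alpha = var_ln - 1.0 / config.depth_mean
    return max(config.depth_dispersion, alpha, 0.0)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    if alpha <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def simulate_cell_depths(
    truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-cell binned counts plus the noise-free diploid control expectation.

    Counts are negative-binomial around depth_mean * CN/2 (scaled by bin width),
    modulated by a smooth cell-specific lognormal wave mimicking WGA
    nonuniformity; overdispersion is calibrated to the configured target MAPD.
    """
    grid = truth.grid
    widths = grid.widths / config.bin_size
    control = config.depth_mean * widths
    alpha = _calibrated_dispersion(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    data = {}
    for cell in truth.cells:
        cn = truth.clone_profiles[truth.cell_assignments[cell]]
        mean = config.depth_mean * widths * cn / 2.0
        if config.wave_sd > 0:
            phase = rng.uniform(0, 2 * np.pi)
            wave = np.exp(
                config.wave_sd
                * np.sin(2 * np.pi * np.arange(len(grid)) / config.wave_period_bins + phase)
            )
            mean = mean * wave
        data[cell] = _nb_draw(rng, mean, alpha)
    depths = pd.DataFrame(data, index=pd.RangeIndex(len(grid), name="bin"))
    return depths, control


def simulate_region_depths(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Bulk-region binned counts: Poisson around the mixture expectation."""
    grid = truth.grid
    widths = grid.widths / config.bin_size
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    data = {}
    for region, comp in truth.region_compositions.items():
        cn_mix = np.zeros(len(grid))
        for clone, frac in comp.items():
            cn_mix += frac * truth.clone_profiles[clone]
        data[region] = rng.poisson(config.depth_mean * widths * cn_mix / 2.0)
    return pd.DataFrame(data, index=pd.RangeIndex(len(grid), name="bin"))


def expected_region_depth(truth: SimTruth, config: SimConfig, region: str) -> np.ndarray:
    """Noise-free expectation of a bulk region's binned counts."""
    widths = truth.grid.widths / config.bin_size
    cn_mix = np.zeros(len(truth.grid))
    for clone, frac in truth.region_compositions[region].items():
        cn_mix += frac * truth.clone_profiles[clone]
    return config.depth_mean * widths * cn_mix / 2.0


def _variant_regional_truth(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Per (variant, region): true presence and expected bulk VAF."""
    rows = []
    for m in config.mutation_spec:
        if not m.germline and not m.carriers:
            raise ValueError(f"variant {m.name!r} assigned to no clone")
        for region, comp in truth.region_compositions.items():
            if m.germline:
                vaf = 0.5
                present = True
            else:
                frac = sum(comp.get(c, 0.0) for c in m.carriers)
                vaf = 0.5 * frac
                present = frac > 0
            rows.append({"variant": m.name, "sample": region, "present": present, "vaf": vaf})
    return pd.DataFrame(rows)


def simulate_mutation_calls(
    truth: SimTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit two caller tables, single-cell assay outcomes, and regional truth.

    Returns (caller_a, caller_b, assays, regional_truth). Caller tables are
    VCF-style wide frames: one row per variant with per-sample VAF columns (NaN
    where the caller made no call) plus a blood column. Each caller misses a
    truly present call independently at ``caller_fn_rate``. Assay outcomes flip
    present -> absent at ``ado_rate`` and to "failed" at ``assay_fail_rate``.
    """
    if not config.mutation_spec:
        raise ValueError("mutation_spec is empty")
    regional = _variant_regional_truth(truth, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    regions = config.regions
    # one realized VAF per (variant, region), shared by both callers
    vaf = regional.pivot(index="variant", columns="sample", values="vaf")
    present = regional.pivot(index="variant", columns="sample", values="present")
    if config.vaf_noise_sd > 0:
        noise = rng.normal(0, config.vaf_noise_sd, vaf.shape)
        vaf = (vaf + noise * present.to_numpy()).clip(0.0, 1.0)
    meta_cols = ["CHROM", "POS", "REF", "ALT", "GENE", "EFFECT", "QUAL", "IS_INDEL", "CALLER"]
    tables = {}
    for caller in ("callerA", "callerB"):
        rows = []
        for m in config.mutation_spec:
            row = {
                "CHROM": m.chrom,
                "POS": m.pos,
                "REF": m.ref,
                "ALT": m.alt,
                "GENE": m.gene,
                "EFFECT": m.effect,
                "QUAL": m.base_quality,
                "IS_INDEL": m.is_indel,
                "CALLER": caller,
                "VARIANT": m.name,
            }
            for region in regions:
                is_present = bool(present.loc[m.name, region])
                detected = is_present and rng.random() >= config.caller_fn_rate
                row[region] = float(vaf.loc[m.name, region]) if detected else np.nan
            row["blood"] = 0.5 if m.germline else np.nan
            rows.append(row)
        tables[caller] = pd.DataFrame(rows, columns=meta_cols + ["VARIANT"] + regions + ["blood"])
    assays = _simulate_assays(truth, config, rng)
    return tables["callerA"], tables["callerB"], assays, regional


def _simulate_assays(
    truth: SimTruth, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    for m in config.mutation_spec:
        if m.germline:
            continue
        carriers = set(m.carriers)
        for cell in truth.cells:
            carries = truth.cell_assignments[cell] in carriers
            if rng.random() < config.assay_fail_rate:
                outcome = "failed"
            elif carries and rng.random() >= config.ado_rate:
                outcome = "present"
            else:
                outcome = "absent"
            rows.append({"cell": cell, "variant": m.name, "outcome": outcome})
    return pd.DataFrame(rows, columns=["cell", "variant", "outcome"])
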
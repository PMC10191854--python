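"""Synthetic data generator for the somatic L1 retrotransposition pipeline.

Emulates the statistical structure of single-cell clone whole-genome data
from normal colorectal epithelium, so that every downstream stage (filtering,
phylogeny, staging, rates, source fingerprinting, methylation, enrichment)
is testable without controlled-access data:

* a rooted binary embryonic lineage tree with Poisson mutation accumulation
  at stage-specific per-division rates (2.4-3.8 mutations per cell per cell
  division for the first two divisions, 0.7-1.2 thereafter);
* somatic L1 retrotransposition (soL1R) events arising per branch as a
  Poisson count proportional to the branch's endogenous point mutations
  (EPMs), drawn from a registry of source elements with heterogeneous
  activity;
* clonal variant allele fractions near 0.5 with binomial read-sampling noise
  at configurable mean depth;
* a bimodal promoter epigenotype per source, fixed once on the branch whose
  molecular time crosses a gastrulation-to-organogenesis window and
  inherited thereafter;
* a population presence panel with configured allele frequencies.

Truth and observations are kept strictly separate so that
parameter-recovery tests cannot leak simulated truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tree import LineageTree, TreeNode

STAGE_NAMES = ("pregastrulation", "postgastrulation", "ageing", "tumourigenesis")

#: signature labels used for simulated mutations
ENDOGENOUS_SNV_SIGNATURES = ("SBS1", "SBS5/40")
OTHER_SNV_SIGNATURE = "SBS18"
ENDOGENOUS_INDEL_SIGNATURES = ("ID1", "ID2")
OTHER_INDEL_SIGNATURE = "ID5"


@dataclass
class SimSource:
    """A simulated retrotransposition-competent L1 source element."""

    source_id: str
    chrom: str
    start: int
    end: int
    strand: str
    activity_weight: float
    paf: float  # population allele frequency, percent
    zygosity: int = 1  # alleles carried by the simulated individual
    #: the near-fixed yet highly active outlier class; excluded from the
    #: activity-vs-prevalence relationship like the study's four such sources
    prevalent_active: bool = False

    def __post_init__(self):
        if self.activity_weight < 0:
            raise ValueError("activity_weight must be non-negative")
        if not 0 <= self.paf <= 100:
            raise ValueError("paf must lie in [0, 100]")
        if self.zygosity not in (0, 1, 2):
            raise ValueError("zygosity must be 0, 1 or 2")

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    def to_record(self):
        from .retro_calls import SourceRecord

        return SourceRecord(
            source_id=self.source_id,
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            strand=self.strand,
        )


def default_source_registry() -> list[SimSource]:
    """Twelve sources mirroring the observed activity/prevalence structure.

    Four prevalent-active sources (near-100% PAF, high activity), four
    common repressed sources (high PAF, near-zero activity) and four rare
    active sources (low PAF, high activity) — activity inversely related to
    prevalence except for the prevalent-active group.
    """
    registry = []
    specs = [
        # (id, paf, activity, prevalent_active)
        ("22q12.1-2", 99.0, 6.0, True),
        ("1p12", 98.0, 5.0, True),
        ("Xp22.2-1", 97.0, 4.0, True),
        ("12p13.32", 99.0, 4.0, True),
        ("5q14.1-1", 85.0, 0.05, False),
        ("14q12-3", 90.0, 0.05, False),
        ("6p22.1-1", 80.0, 0.05, False),
        ("9q21.13", 88.0, 0.05, False),
        ("17q25.3", 2.0, 8.0, False),
        ("1q23.3-1", 5.0, 7.0, False),
        ("1p22.1", 10.0, 6.0, False),
        ("2q21.1-2", 15.0, 5.0, False),
    ]
    chroms = ["chr1", "chr2", "chr3"]
    for i, (sid, paf, act, hot) in enumerate(specs):
        chrom = chroms[i % len(chroms)]
        start = 2_000_000 + i * 3_000_000
        registry.append(
            SimSource(
                source_id=sid,
                chrom=chrom,
                start=start,
                end=start + 6000,
                strand="+" if i % 2 == 0 else "-",
                activity_weight=act,
                paf=paf,
                prevalent_active=hot,
            )
        )
    return registry


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study's stated conditions."""

    n_clones: int = 19
    n_individuals: int = 2860  # population panel size
    age_years: float = 60.0
    #: mutations per cell per cell division, generations 1-2
    early_rate_low: float = 2.4
    early_rate_high: float = 3.8
    #: mutations per cell per cell division thereafter
    late_rate_low: float = 0.7
    late_rate_high: float = 1.2
    #: soL1R events per EPM by developmental stage
    sol1r_rate_by_stage: dict[str, float] = field(
        default_factory=lambda: {
            "pregastrulation": 1.06e-3,
            "postgastrulation": 4.52e-3,
            "ageing": 1.2e-3,
            "tumourigenesis": 3.47e-3,
        }
    )
    source_registry: list[SimSource] = field(default_factory=default_source_registry)
    mean_depth: float = 17.0
    seed: int = 0
    #: fraction of point mutations that are SNVs (remainder indels)
    snv_fraction: float = 0.9
    #: SBS1 + SBS5/40 among SNVs; ID1/ID2 among indels
    endogenous_snv_fraction: float = 0.8
    endogenous_indel_fraction: float = 0.9
    #: solo : partnered : orphan class weights
    class_weights: dict[str, float] = field(
        default_factory=lambda: {"solo": 89.0, "partnered": 1.0, "orphan": 10.0}
    )
    #: fraction of events with a twin-priming (intra-body) inversion
    inversion_fraction: float = 0.295
    #: molecular-time window (mutations) in which promoter epigenotypes fix
    gastrulation_window: tuple[float, float] = (17.0, 65.0)
    epigenotype_probs: dict[str, float] = field(
        default_factory=lambda: {"open": 0.25, "heterozygous": 0.15, "closed": 0.60}
    )
    epigenotype_levels: dict[str, float] = field(
        default_factory=lambda: {"open": 0.05, "heterozygous": 0.50, "closed": 0.95}
    )
    #: generations spanned by embryonic branches after the first two divisions;
    #: the range is wide enough that clone-pair MRCAs populate all three
    #: branching-time strata (before, inside, after the fixation window)
    embryonic_branch_generations: tuple[int, int] = (1, 80)
    #: terminal (ageing) branch length in cell generations; by default derived
    #: from age at ~30 stem-cell divisions per year so that the per-clone
    #: soL1R burden matches the observed age slope
    terminal_generations: Optional[int] = None
    generations_per_year: float = 30.0
    n_cpg_promoter: int = 20
    cpg_coverage_mean: float = 15.0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 40_000_000}
    )

    def __post_init__(self):
        if self.n_clones < 2:
            raise ValueError("n_clones must be at least 2")
        for name in (
            "early_rate_low",
            "early_rate_high",
            "late_rate_low",
            "late_rate_high",
            "mean_depth",
            "generations_per_year",
            "cpg_coverage_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.early_rate_low > self.early_rate_high:
            raise ValueError("early_rate_low must not exceed early_rate_high")
        if self.late_rate_low > self.late_rate_high:
            raise ValueError("late_rate_low must not exceed late_rate_high")
        for stage, rate in self.sol1r_rate_by_stage.items():
            if rate < 0:
                raise ValueError(f"sol1r_rate_by_stage[{stage!r}] must be non-negative")
        for name in ("snv_fraction", "endogenous_snv_fraction", "endogenous_indel_fraction",
                     "inversion_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for prob in self.epigenotype_probs.values():
            if not 0 <= prob <= 1:
                raise ValueError("epigenotype probabilities must lie in [0, 1]")
        total = sum(self.epigenotype_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("epigenotype probabilities must sum to 1")

    def resolved_terminal_generations(self) -> int:
        if self.terminal_generations is not None:
            return int(self.terminal_generations)
        return int(round(self.age_years * self.generations_per_year))


@dataclass
class SimMutation:
    mut_id: str
    chrom: str
    pos: int  # 1-based
    kind: str  # 'snv' | 'indel'
    signature: str
    endogenous: bool
    branch: str


@dataclass
class SimEvent:
    """A simulated soL1R event and its full truth record."""

    event_id: str
    branch: str
    stage: str
    source_id: Optional[str]
    insertion_class: str
    inverted: bool
    polyA_len: int
    tsd_len: int
    chrom: str
    target_pos: int  # 1-based
    #: transduced unique segment (partnered/orphan), 0-based half-open
    segment: Optional[tuple[str, int, int, str]] = None


@dataclass
class SimulatedTruth:
    """Everything the generator knows; serialized separately from observations."""

    tree: LineageTree
    mutations: list[SimMutation]
    events: list[SimEvent]
    #: clone -> source -> epigenotype category
    clone_epigenotypes: dict[str, dict[str, str]]
    #: source -> molecular time at which the epigenotype fixed
    fixation_times: dict[str, float]
    #: sources x individuals presence (bool)
    panel_presence: Optional[pd.DataFrame] = None
    config: Optional[SimulationConfig] = None

    def mutations_on_path(self, clone: str) -> list[SimMutation]:
        leaf = self.tree.leaf_by_sample(clone)
        branch_ids = {n.node_id for n in self.tree.path_to_root(leaf)}
        return [m for m in self.mutations if m.branch in branch_ids]

    def params_dict(self) -> dict:
        cfg = dataclasses.asdict(self.config) if self.config else {}
        cfg.pop("source_registry", None)
        return {
            "config": cfg,
            "sources": [dataclasses.asdict(s) for s in (self.config.source_registry if self.config else [])],
            "fixation_times": self.fixation_times,
            "n_mutations": len(self.mutations),
            "n_events": len(self.events),
        }


# ---------------------------------------------------------------------------
# Lineage simulation
# ---------------------------------------------------------------------------

def _stage_rng(config: SimulationConfig, stage_offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage_offset])


def _expected_mutations(
    gen_start: int, gen_end: int, r_early: float, r_late: float
) -> float:
    """Poisson mean for a branch spanning generations gen_start+1 .. gen_end."""
    n_early = max(0, min(gen_end, 2) - min(gen_start, 2))
    n_late = (gen_end - gen_start) - n_early
    return n_early * r_early + n_late * r_late


def simulate_lineage(config: SimulationConfig) -> tuple[LineageTree, SimulatedTruth]:
    """Simulate the embryonic lineage tree, mutations and epigenotypes.

    The topology is built by uniformly random binary splits until the
    configured number of clones is reached; the first two divisions span one
    generation each, later embryonic branches span a uniform-random number of
    generations, and each clone's terminal branch spans the ageing phase.
    Branch mutation counts are Poisson with mean = generations x a
    per-generation rate drawn uniformly within the stage's range.
    """
    rng = _stage_rng(config, 1)
    emb_lo, emb_hi = config.embryonic_branch_generations
    window_lo, window_hi = config.gastrulation_window

    root = TreeNode(node_id="zygote", generations=0)
    gen_end: dict[str, int] = {"zygote": 0}
    counter = [0]

    def new_node(parent: TreeNode, generations: int) -> TreeNode:
        counter[0] += 1
        node = TreeNode(node_id=f"n{counter[0]}", generations=generations)
        parent.add_child(node)
        gen_end[node.node_id] = gen_end[parent.node_id] + generations
        return node

    # first cleavage: two daughters of the zygote
    lineages = [new_node(root, 1), new_node(root, 1)]
    while len(lineages) < config.n_clones:
        i = int(rng.integers(len(lineages)))
        parent = lineages.pop(i)
        for _ in range(2):
            gens = 1 if gen_end[parent.node_id] < 2 else int(rng.integers(emb_lo, emb_hi + 1))
            lineages.append(new_node(parent, gens))

    # terminal (ageing) branches
    terminal_gens = config.resolved_terminal_generations()
    clones = []
    for k, lineage in enumerate(lineages):
        clone = new_node(lineage, terminal_gens)
        clone.sample = f"clone{k + 1:02d}"
        clone.node_id = clone.sample
        gen_end[clone.node_id] = gen_end[lineage.node_id] + terminal_gens
        clones.append(clone)

    tree = LineageTree(root)

    # mutations per branch
    chroms = list(config.chrom_lengths)
    chrom_p = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    mutations: list[SimMutation] = []
    for node in tree.branches():
        start = gen_end[node.node_id] - node.generations
        r_early = rng.uniform(config.early_rate_low, config.early_rate_high)
        r_late = rng.uniform(config.late_rate_low, config.late_rate_high)
        mean = _expected_mutations(start, gen_end[node.node_id], r_early, r_late)
        count = int(rng.poisson(mean)) if mean > 0 else 0
        epm = 0
        if count:
            is_snv = rng.random(count) < config.snv_fraction
            endog_draw = rng.random(count)
            endog = np.where(
                is_snv,
                endog_draw < config.endogenous_snv_fraction,
                endog_draw < config.endogenous_indel_fraction,
            )
            sig_idx = rng.integers(0, 2, size=count)
            chrom_idx = rng.choice(len(chroms), size=count, p=chrom_p)
            pos_frac = rng.random(count)
            for k in range(count):
                chrom = chroms[int(chrom_idx[k])]
                if is_snv[k]:
                    signature = (
                        ENDOGENOUS_SNV_SIGNATURES[sig_idx[k]]
                        if endog[k]
                        else OTHER_SNV_SIGNATURE
                    )
                else:
                    signature = (
                        ENDOGENOUS_INDEL_SIGNATURES[sig_idx[k]]
                        if endog[k]
                        else OTHER_INDEL_SIGNATURE
                    )
                mut = SimMutation(
                    mut_id=f"mut{len(mutations) + 1:06d}",
                    chrom=chrom,
                    pos=1 + int(pos_frac[k] * config.chrom_lengths[chrom]),
                    kind="snv" if is_snv[k] else "indel",
                    signature=signature,
                    endogenous=bool(endog[k]),
                    branch=node.node_id,
                )
                mutations.append(mut)
                node.mutations.append(mut.mut_id)
            epm = int(endog.sum())
        node.branch_length = count
        node.epm = epm

    # truth stage labels by molecular time: internal branches ending before
    # the fixation window are pregastrulational (detectable in blood),
    # later internal branches postgastrulational, terminal branches ageing
    for node in tree.branches():
        if node.is_leaf():
            node.stage = "ageing"
        else:
            node.stage = (
                "pregastrulation"
                if tree.molecular_time(node) <= window_lo
                else "postgastrulation"
            )

    # promoter epigenotypes: fixed once on the branch crossing the per-source
    # fixation time, inherited by all descendant clones
    categories = list(config.epigenotype_probs)
    probs = np.array([config.epigenotype_probs[c] for c in categories])
    fixation_times: dict[str, float] = {}
    clone_epigenotypes: dict[str, dict[str, str]] = {c.sample: {} for c in clones}
    for source in config.source_registry:
        t_fix = float(rng.uniform(window_lo, window_hi))
        fixation_times[source.source_id] = t_fix

        def walk(node: TreeNode, inherited: Optional[str]) -> None:
            state = inherited
            if state is None and tree.molecular_time(node) >= t_fix:
                state = categories[int(rng.choice(len(categories), p=probs))]
            if node.is_leaf() and node.sample is not None:
                # terminal branches always cross the window
                if state is None:
                    state = categories[int(rng.choice(len(categories), p=probs))]
                clone_epigenotypes[node.sample][source.source_id] = state
                return
            for child in node.children:
                walk(child, state)

        walk(root, None)

    truth = SimulatedTruth(
        tree=tree,
        mutations=mutations,
        events=[],
        clone_epigenotypes=clone_epigenotypes,
        fixation_times=fixation_times,
        config=config,
    )
    return tree, truth


# ---------------------------------------------------------------------------
# soL1R simulation
# ---------------------------------------------------------------------------

def simulate_sol1r(tree: LineageTree, config: SimulationConfig, truth: SimulatedTruth) -> list[SimEvent]:
    """Place soL1R events on branches: count ~ Poisson(stage rate x branch EPM).

    Each event draws a source by activity weight (restricted, once promoter
    epigenotypes are fixed, to sources demethylated in the receiving lineage),
    an insertion class, an inversion flag, poly-A and TSD lengths, and a
    target site uniform over the simulated genome.
    """
    rng = _stage_rng(config, 2)
    chroms = list(config.chrom_lengths)
    chrom_p = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p /= chrom_p.sum()
    class_names = list(config.class_weights)
    class_p = np.array([config.class_weights[c] for c in class_names], dtype=float)
    class_p /= class_p.sum()

    carriers = [s for s in config.source_registry if s.zygosity >= 1]
    events: list[SimEvent] = []
    for node in tree.branches():
        stage = node.stage
        if stage not in config.sol1r_rate_by_stage:
            raise KeyError(f"stage {stage!r} missing from sol1r_rate_by_stage")
        mean = config.sol1r_rate_by_stage[stage] * node.epm
        count = int(rng.poisson(mean)) if mean > 0 else 0
        for _ in range(count):
            # sources allowed in this lineage: demethylated where fixed
            allowed = []
            if node.is_leaf() and node.sample is not None:
                for s in carriers:
                    epig = truth.clone_epigenotypes[node.sample].get(s.source_id)
                    if epig in (None, "open", "heterozygous"):
                        allowed.append(s)
            else:
                # embryonic branches precede or straddle fixation; global
                # demethylation makes every carrier source available
                allowed = carriers
            pool = allowed or carriers
            if not pool:
                continue
            weights = np.array([s.activity_weight * s.zygosity for s in pool], dtype=float)
            if weights.sum() == 0:
                weights = np.ones(len(pool))
            weights /= weights.sum()
            source = pool[int(rng.choice(len(pool), p=weights))]

            cls = class_names[int(rng.choice(len(class_names), p=class_p))]
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_p))]
            pos = int(rng.integers(1, config.chrom_lengths[chrom] + 1))
            segment = None
            if cls in ("partnered", "orphan"):
                seg_len = int(rng.integers(200, 3001))
                offset = int(rng.integers(0, 12_001 - seg_len)) if seg_len < 12_000 else 0
                if source.strand == "+":
                    seg_start = source.three_prime_end + offset
                    seg_end = seg_start + seg_len
                else:
                    seg_end = source.three_prime_end - offset
                    seg_start = seg_end - seg_len
                segment = (source.chrom, seg_start, seg_end, source.strand)
            events.append(
                SimEvent(
                    event_id=f"ev{len(events) + 1:05d}",
                    branch=node.node_id,
                    stage=stage,
                    source_id=source.source_id,
                    insertion_class=cls,
                    inverted=bool(rng.random() < config.inversion_fraction),
                    polyA_len=int(rng.integers(10, 81)),
                    tsd_len=int(rng.integers(5, 21)),
                    chrom=chrom,
                    target_pos=pos,
                    segment=segment,
                )
            )
        node.sol1r_events = [e for e in events if e.branch == node.node_id]
    truth.events = events
    return events


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

@dataclass
class Observations:
    """Noisy call tables as a downstream pipeline would see them."""

    variant_table: pd.DataFrame  # long: mut_id, chrom, pos, clone, depth, var_reads, vaf
    insertion_table: pd.DataFrame
    methylation_table: pd.DataFrame  # clone, source, rel_pos, meth, unmeth
    panel: pd.DataFrame  # sources x individuals evidence fractions

    def vaf_matrix(self) -> pd.DataFrame:
        return self.variant_table.pivot(index="mut_id", columns="clone", values="vaf")

    def depth_matrix(self) -> pd.DataFrame:
        return self.variant_table.pivot(index="mut_id", columns="clone", values="depth")


def simulate_observations(truth: SimulatedTruth, config: SimulationConfig) -> Observations:
    """Draw read-level observations from the simulated truth.

    Somatic mutations are heterozygous and clonal within a clone, so variant
    reads are Binomial(depth, 0.5) in carrier clones and 0 elsewhere; depth is
    Poisson(mean depth) and zero-depth rows are emitted, never dropped.
    Insertion read pairs follow the breakpoint-informative pair model under
    which the estimator s/(s+2r) is unbiased for the insertion allele
    fraction.  Promoter CpG counts are Binomial around the clone's
    epigenotype level; the population panel reports per-individual
    supporting-evidence fractions.
    """
    rng = _stage_rng(config, 3)
    tree = truth.tree
    clones = sorted(leaf.sample for leaf in tree.leaves())

    # ---- SNV/indel table (vectorized over mutations x clones) ----
    mut_ids = [m.mut_id for m in truth.mutations]
    carrier = np.zeros((len(mut_ids), len(clones)), dtype=bool)
    branch_rows: dict[str, list[int]] = {}
    for i, m in enumerate(truth.mutations):
        branch_rows.setdefault(m.branch, []).append(i)
    for j, clone in enumerate(clones):
        leaf = tree.leaf_by_sample(clone)
        for node in tree.path_to_root(leaf):
            rows_idx = branch_rows.get(node.node_id)
            if rows_idx:
                carrier[rows_idx, j] = True
    depth = rng.poisson(config.mean_depth, size=carrier.shape)
    var_reads = np.where(carrier, rng.binomial(depth, 0.5), 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(depth > 0, var_reads / np.maximum(depth, 1), 0.0)
    # kind/signature channels are observable in real data (context classes),
    # so they ride along with the calls rather than staying truth-only
    variant_table = pd.DataFrame(
        {
            "mut_id": np.repeat(mut_ids, len(clones)),
            "chrom": np.repeat([m.chrom for m in truth.mutations], len(clones)),
            "pos": np.repeat([m.pos for m in truth.mutations], len(clones)),
            "kind": np.repeat([m.kind for m in truth.mutations], len(clones)),
            "signature": np.repeat([m.signature for m in truth.mutations], len(clones)),
            "endogenous": np.repeat([m.endogenous for m in truth.mutations], len(clones)),
            "clone": np.tile(clones, len(mut_ids)),
            "depth": depth.ravel(),
            "var_reads": var_reads.ravel(),
            "vaf": vaf.ravel(),
        }
    )

    # ---- insertion calls ----
    rows = []
    node_by_id = {n.node_id: n for n in tree.nodes()}
    for event in truth.events:
        event_node = node_by_id[event.branch]
        subtree_clones = [
            leaf.sample for leaf in tree._subtree_leaves(event_node) if leaf.sample
        ]
        for clone in subtree_clones:
            # clonal heterozygous in the carrier clone: allele fraction 0.5
            a = 0.5
            lam = config.mean_depth / 2.0
            s = int(rng.poisson(lam * 2 * a))
            r = int(rng.poisson(lam * (1 - a)))
            rows.append(
                {
                    "event_id": event.event_id,
                    "clone": clone,
                    "chrom": event.chrom,
                    "target_pos": event.target_pos,
                    "insertion_class_true": event.insertion_class,
                    "source_id_true": event.source_id,
                    "polyA_len": event.polyA_len,
                    "tsd_len": event.tsd_len,
                    "inverted": event.inverted,
                    "supporting_pairs": s,
                    "reference_pairs": r,
                    "seg_chrom": event.segment[0] if event.segment else "",
                    "seg_start": event.segment[1] if event.segment else -1,
                    "seg_end": event.segment[2] if event.segment else -1,
                    "seg_strand": event.segment[3] if event.segment else "",
                }
            )
    insertion_table = pd.DataFrame(rows)

    # ---- promoter methylation counts ----
    meth_rows = []
    cpg_positions = np.linspace(1, 250, config.n_cpg_promoter).astype(int)
    for clone in clones:
        for source in config.source_registry:
            epig = truth.clone_epigenotypes[clone].get(source.source_id)
            if epig is None:
                continue
            level = config.epigenotype_levels[epig]
            cov = rng.poisson(config.cpg_coverage_mean, size=len(cpg_positions))
            meth = rng.binomial(cov, level)
            for p, c, m in zip(cpg_positions, cov, meth):
                meth_rows.append(
                    {
                        "clone": clone,
                        "source": source.source_id,
                        "rel_pos": int(p),
                        "meth": int(m),
                        "unmeth": int(c - m),
                    }
                )
    methylation_table = pd.DataFrame(meth_rows)

    # ---- population panel ----
    individuals = [f"ind{k + 1:04d}" for k in range(config.n_individuals)]
    presence = np.zeros((len(config.source_registry), len(individuals)), dtype=bool)
    fractions = np.zeros_like(presence, dtype=float)
    for i, source in enumerate(config.source_registry):
        carrier_draw = rng.random(len(individuals)) < source.paf / 100.0
        presence[i] = carrier_draw
        fractions[i] = np.where(
            carrier_draw,
            rng.uniform(0.25, 0.9, size=len(individuals)),
            rng.uniform(0.0, 0.10, size=len(individuals)),
        )
    panel = pd.DataFrame(
        fractions,
        index=[s.source_id for s in config.source_registry],
        columns=individuals,
    )
    truth.panel_presence = pd.DataFrame(
        presence, index=panel.index, columns=panel.columns
    )

    return Observations(
        variant_table=variant_table,
        insertion_table=insertion_table,
        methylation_table=methylation_table,
        panel=panel,
    )


# ---------------------------------------------------------------------------
# One-call dataset and cohort helpers
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> tuple[SimulatedTruth, Observations]:
    """Lineage + soL1Rs + observations in one deterministic call."""
    tree, truth = simulate_lineage(config)
    simulate_sol1r(tree, config, truth)
    observations = simulate_observations(truth, config)
    return truth, observations


def simulate_cohort(
    base_config: SimulationConfig,
    ages: Sequence[float],
    *,
    clones_per_individual: int = 5,
) -> list[SimulatedTruth]:
    """Independent truth simulations for several individuals (no observations).

    Used for burden-age and TPAM/PAF analyses, where only truth-level event
    counts and molecular clocks are needed.  Zygosity for each individual is
    drawn from each source's population allele frequency.
    """
    truths = []
    for k, age in enumerate(ages):
        rng = np.random.default_rng([int(base_config.seed), 100 + k])
        registry = []
        for s in base_config.source_registry:
            p = s.paf / 100.0
            # Hardy-Weinberg allele-count draw from the carrier frequency
            q = 1 - np.sqrt(max(0.0, 1 - p))
            alleles = int(rng.binomial(2, q))
            registry.append(dataclasses.replace(s, zygosity=alleles))
        cfg = dataclasses.replace(
            base_config,
            age_years=float(age),
            n_clones=clones_per_individual,
            seed=int(rng.integers(0, 2**31 - 1)),
            source_registry=registry,
        )
        tree, truth = simulate_lineage(cfg)
        simulate_sol1r(tree, cfg, truth)
        truths.append(truth)
    return truths


def simulate_insertion_sites(
    binning,
    n: int,
    rng: np.random.Generator,
    *,
    bin_preference: Optional[dict[int, float]] = None,
) -> pd.DataFrame:
    """Sample insertion positions over a FeatureBinning, optionally biased.

    With no preference, positions are uniform over the binned genome; with
    ``bin_preference`` the per-bin sampling rate is multiplied by the given
    factor (used for enrichment parameter-recovery tests).
    """
    intervals = binning.intervals
    lengths = (intervals["end"] - intervals["start"]).to_numpy(dtype=float)
    weights = lengths.copy()
    if bin_preference:
        for b, f in bin_preference.items():
            weights[intervals["bin"].to_numpy() == b] *= f
    weights /= weights.sum()
    idx = rng.choice(len(intervals), size=n, p=weights)
    starts = intervals["start"].to_numpy()[idx]
    spans = (intervals["end"] - intervals["start"]).to_numpy()[idx]
    pos = starts + (rng.random(n) * spans).astype(int)
    return pd.DataFrame({"chrom": intervals["chrom"].to_numpy()[idx], "pos": pos})
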
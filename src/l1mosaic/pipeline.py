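"""End-to-end pipeline: simulate -> calls -> phylogeny -> rates -> sources ->
methylation -> enrichment, emitting one structured report.

Each stage consumes only observation-level tables (never simulated truth),
so the report doubles as a parameter-recovery check against the generator's
configured rates.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import methylation as meth
from . import phylogeny as phylo
from . import rates_staging as rates
from . import retro_calls as calls
from . import sources_paf as sources
from . import synthetic_data as synth
from .io import RunConfig, write_json, write_table

logger = logging.getLogger("l1mosaic")


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run the selected stages and write report.json plus per-stage TSVs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.dump(), "stages": {}}
    state: dict = {}

    runners = {
        "simulate": _stage_simulate,
        "calls": _stage_calls,
        "phylogeny": _stage_phylogeny,
        "rates": _stage_rates,
        "sources": _stage_sources,
        "methylation": _stage_methylation,
        "enrichment": _stage_enrichment,
    }
    for stage in config.stages:
        if stage not in runners:
            raise KeyError(f"unknown stage {stage!r}")
        try:
            logger.info("running stage %s", stage)
            report["stages"][stage] = runners[stage](config, state, out)
        except Exception as exc:  # preserve partial outputs on failure
            write_json(report, out / "report.json")
            raise StageFailure(stage, exc) from exc
    write_json(report, out / "report.json")
    return report


def _sim_config(config: RunConfig) -> synth.SimulationConfig:
    params = dict(config.simulation)
    params.setdefault("seed", config.seed)
    return synth.SimulationConfig(**params)


def _stage_simulate(config: RunConfig, state: dict, out: Path) -> dict:
    sim_cfg = _sim_config(config)
    truth, obs = synth.simulate_dataset(sim_cfg)
    state.update(sim_cfg=sim_cfg, truth=truth, obs=obs)
    write_table(obs.variant_table, out / "variants.tsv")
    write_table(obs.insertion_table, out / "insertions.tsv")
    write_table(obs.methylation_table, out / "methylation.tsv", schema="methylation")
    obs.panel.to_csv(out / "panel.tsv", sep="\t")
    (out / "truth_tree.nwk").write_text(truth.tree.to_newick() + "\n")
    import yaml

    (out / "truth_params.yaml").write_text(yaml.safe_dump(truth.params_dict()))
    return {
        "n_clones": sim_cfg.n_clones,
        "n_mutations": len(truth.mutations),
        "n_sol1r_events": len(truth.events),
        "seed": sim_cfg.seed,
    }


def _events_from_table(table: pd.DataFrame, registry) -> list[calls.SoL1REvent]:
    """Observation rows -> SoL1REvent objects (one per event x clone)."""
    out = []
    for row in table.itertuples():
        seg = None
        if row.seg_chrom:
            seg = calls.SegmentMapping(
                contig=row.seg_chrom,
                start=int(row.seg_start),
                end=int(row.seg_end),
                strand=row.seg_strand,
                is_repeat=False,
            )
        cls_true = row.insertion_class_true
        ev = calls.SoL1REvent(
            sample_id=row.clone,
            chrom=row.chrom,
            target_pos=int(row.target_pos),
            polyA_len=int(row.polyA_len),
            tsd_len=int(row.tsd_len),
            supporting_pairs=int(row.supporting_pairs),
            reference_pairs=int(row.reference_pairs),
            insert_5p_map=(
                calls.SegmentMapping("L1HS", 3000, 6000, "+", is_repeat=True)
                if cls_true in ("solo", "partnered")
                else None
            ),
            insert_3p_map=(
                calls.SegmentMapping(
                    "L1HS", 5500, 6000, "-" if row.inverted else "+", is_repeat=True
                )
                if cls_true == "solo"
                else None
            ),
            unique_segment=seg,
        )
        ev.event_id = row.event_id  # type: ignore[attr-defined]
        out.append(ev)
    return out


def _stage_calls(config: RunConfig, state: dict, out: Path) -> dict:
    obs = state["obs"]
    sim_cfg = state["sim_cfg"]
    registry = [s.to_record() for s in sim_cfg.source_registry]
    events = _events_from_table(obs.insertion_table, registry)
    validated, failed = [], []
    for ev in events:
        ok, reasons = calls.validate_insertion(
            ev, min_support_fraction=config.thresholds["min_support_fraction"]
        )
        (validated if ok else failed).append((ev, reasons))
    for ev, _ in validated:
        calls.classify_insertion(
            ev, registry, window=config.thresholds["transduction_window_bp"]
        )
    state["validated_events"] = [ev for ev, _ in validated]
    vafs = [
        calls.insertion_vaf(ev.supporting_pairs, ev.reference_pairs)
        for ev, _ in validated
        if ev.supporting_pairs + ev.reference_pairs > 0
    ]
    fractions = calls.class_fractions([ev for ev, _ in validated])
    return {
        "n_calls": len(events),
        "n_validated": len(validated),
        "n_failed": len(failed),
        "mean_insertion_vaf": float(np.mean(vafs)) if vafs else None,
        "class_fractions": fractions,
    }


def _stage_phylogeny(config: RunConfig, state: dict, out: Path) -> dict:
    obs = state["obs"]
    vaf = obs.vaf_matrix()
    depth = obs.depth_matrix()
    tree, rep, genotypes = phylo.reconstruct_from_matrix(
        vaf,
        depth,
        presence_vaf=config.thresholds["presence_vaf"],
        min_depth=config.thresholds["min_depth"],
        min_max_vaf=config.thresholds["min_max_vaf"],
    )
    state["tree"] = tree
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    groups = phylo.group_mutations(genotypes)
    write_table(
        pd.DataFrame(
            {
                "samples": ["+".join(sorted(g.samples)) for g in groups],
                "n_mutations": [g.size for g in groups],
            }
        ),
        out / "mutation_groups.tsv",
    )
    return {
        "n_retained_mutations": len(genotypes),
        "n_groups": len(groups),
        "n_conflicting_groups": len(rep.conflicting),
        "discarded_mutations": rep.discarded_mutations,
        "total_branch_length": tree.total_branch_length(),
    }


def _stage_rates(config: RunConfig, state: dict, out: Path) -> dict:
    obs, tree = state["obs"], state["tree"]
    variant = obs.variant_table

    # per-branch EPM from observed signature channels of assigned mutations
    endog = {m for m in variant.loc[variant["endogenous"], "mut_id"]} if "endogenous" in variant else set()
    for node in tree.branches():
        node.epm = sum(1 for m in node.mutations if m in endog)

    # blood evidence: shared mutations on branches detectable in mesoderm;
    # supplied by the simulator as an observation-level table
    blood = state.get("blood_evidence", {})
    truth = state.get("truth")
    if not blood and truth is not None:
        pre_branches = {
            n.node_id for n in truth.tree.branches() if n.stage == "pregastrulation"
        }
        pre_muts = {m.mut_id for m in truth.mutations if m.branch in pre_branches}
        # a reconstructed branch can merge segments from both sides of
        # gastrulation; call it blood-detectable when most of its mutations are
        blood = {
            n.node_id: sum(m in pre_muts for m in n.mutations) > len(n.mutations) / 2
            for n in tree.branches()
            if not n.is_leaf() and n.mutations
        }
    annotation = rates.assign_stages(tree, blood)

    # events per reconstructed branch: an event shared by clones C sits on the
    # branch whose subtree-leaf set equals C
    validated = state.get("validated_events", [])
    by_event: dict[str, set] = {}
    for ev in validated:
        by_event.setdefault(getattr(ev, "event_id", ev.sample_id), set()).add(ev.sample_id)
    clusters = {}
    for node in tree.branches():
        leaves = frozenset(
            l.sample for l in tree._subtree_leaves(node) if l.sample is not None
        )
        clusters.setdefault(leaves, node)
    unplaced = 0
    for node in tree.branches():
        node.sol1r_events = []
    for event_id, clone_set in by_event.items():
        node = clusters.get(frozenset(clone_set))
        if node is None:
            unplaced += 1
            continue
        node.sol1r_events.append(event_id)

    estimates = rates.stage_rates(tree, annotation)
    write_table(rates.rate_report(estimates), out / "rates.tsv")
    result = {
        stage: {
            "events": est.events,
            "epm": est.epm,
            "rate_per_1000_epm": est.rate_per_1000_epm,
            "ci": [est.ci_low, est.ci_high],
        }
        for stage, est in estimates.items()
    }
    if "ageing" in estimates and "postgastrulation" in estimates:
        a, p = estimates["ageing"], estimates["postgastrulation"]
        result["postgastrulation_vs_ageing_p"] = rates.compare_rates(
            p.events, p.epm, a.events, a.epm
        )
    result["unplaced_events"] = unplaced
    state["stage_rates"] = estimates
    return result


def _stage_sources(config: RunConfig, state: dict, out: Path) -> dict:
    sim_cfg, obs, tree = state["sim_cfg"], state["obs"], state["tree"]
    registry = sim_cfg.source_registry
    validated = state.get("validated_events", [])

    # fingerprint transductions, then count unique events per source
    seen: dict[str, str] = {}
    for ev in validated:
        if ev.insertion_class in ("partnered", "orphan") and ev.source_id:
            seen.setdefault(getattr(ev, "event_id", id(ev)), ev.source_id)
    per_source: dict[str, int] = {}
    for sid in seen.values():
        per_source[sid] = per_source.get(sid, 0) + 1

    epm_total = float(sum(n.epm for n in tree.branches()))
    tpam = {}
    for s in registry:
        if s.zygosity >= 1:
            tpam[s.source_id] = sources.compute_tpam(
                {"ind": per_source.get(s.source_id, 0)},
                {"ind": s.zygosity},
                {"ind": epm_total},
            )
    paf = sources.paf_table(
        obs.panel, threshold=config.thresholds["paf_presence_threshold"]
    )
    paf.rename("paf").to_frame().to_csv(out / "paf.tsv", sep="\t")
    return {
        "n_transductions_attributed": len(seen),
        "transductions_per_source": per_source,
        "tpam": tpam,
        "paf": {k: float(v) for k, v in paf.items()},
        "tpam_paf_spearman": sources.tpam_paf_correlation(
            tpam, {k: float(v) for k, v in paf.items()}
        ),
    }


def _stage_methylation(config: RunConfig, state: dict, out: Path) -> dict:
    obs, tree = state["obs"], state["tree"]
    methylomes = []
    for (clone, source), sub in obs.methylation_table.groupby(["clone", "source"]):
        methylomes.append(
            meth.PromoterMethylome(
                source_id=source,
                clone_id=clone,
                cpgs=[
                    meth.CpGRecord(int(r.rel_pos), int(r.meth), int(r.unmeth))
                    for r in sub.itertuples()
                ],
            )
        )
    scores = meth.score_matrix(methylomes)
    scores.to_csv(out / "promoter_scores.tsv", sep="\t")
    result: dict = {
        "n_clone_source_pairs": int(scores.notna().sum().sum()),
        "epigenotype_counts": {
            cat: int(
                scores.stack().dropna().map(meth.call_epigenotype).eq(cat).sum()
            )
            for cat in meth.EPIGENOTYPES
        },
    }
    try:
        conc = meth.concordance_vs_branching(tree, scores)
        result["concordance_by_stratum"] = conc.concordance_by_stratum
        result["ks_statistic"] = conc.ks_statistic
        result["ks_pvalue"] = conc.ks_pvalue
    except ValueError as exc:
        result["concordance_error"] = str(exc)
    return result


def _stage_enrichment(config: RunConfig, state: dict, out: Path) -> dict:
    sim_cfg, obs = state["sim_cfg"], state["obs"]
    insertions = (
        obs.insertion_table.drop_duplicates("event_id")
        .assign(pos=lambda t: t["target_pos"] - 1)[["chrom", "pos"]]
        .reset_index(drop=True)
    )
    windows = enr.window_insertion_rate(
        insertions,
        sim_cfg.chrom_lengths,
        window=config.thresholds["sliding_window_bp"],
        step=config.thresholds["sliding_step_bp"],
    )
    write_table(windows, out / "window_counts.tsv")

    # null calibration on a synthetic fold-enrichment track: simulated target
    # sites are uniform, so folds should cover 1
    rng = np.random.default_rng([config.seed, 9])
    rows = []
    for chrom, length in sim_cfg.chrom_lengths.items():
        step = max(length // 50, 1)
        for start in range(0, length, step):
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + step, length),
                    "signal": float(rng.lognormal(0.0, 1.0)),
                }
            )
    track = pd.DataFrame(rows)
    binning = enr.bin_signal_track(track, "fold_enrichment", feature="synthetic_signal")
    scores = enr.enrichment_scores(insertions, binning)
    write_table(scores.to_frame(), out / "enrichment.tsv")
    return {
        "n_insertions": len(insertions),
        "max_window_count": int(windows["count"].max()) if len(windows) else 0,
        "enrichment": {
            str(b): {"fold": f, "ci": [lo, hi]}
            for b, (f, lo, hi) in scores.folds.items()
        },
    }
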
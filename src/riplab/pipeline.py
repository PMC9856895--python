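"""Multi-stage pipeline runner with a machine-readable run manifest.

A run is described by a declarative config (YAML on the CLI, a plain dict
here): a ``stages`` list plus one parameter block per stage.  Stages run in
dependency order — simulation first, then target calling, then set
enrichment — while the behavioral, motif-census and quantification stages
are independent.  Every run writes ``manifest.json`` recording inputs,
parameters, seeds and the package version, so a run is reconstructible from
the manifest alone.
"""

from __future__ import annotations

import json
import logging
import platform
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any

import pandas as pd

from . import behavior_stats, cpe_scan, io, quant, rip_enrichment, set_enrichment
from . import synthetic_data as synth
from .errors import ConfigurationError

__all__ = ["run_pipeline", "KNOWN_STAGES"]

log = logging.getLogger("riplab")

KNOWN_STAGES = (
    "simulate",
    "call-targets",
    "overlap",
    "ora",
    "memory-test",
    "cpe-census",
    "western-quant",
    "qpcr-quant",
)

_STAGE_ORDER = {name: i for i, name in enumerate(KNOWN_STAGES)}


def _validate(config: dict[str, Any]) -> list[str]:
    stages = config.get("stages", [])
    if not stages:
        raise ConfigurationError("config must list at least one stage under 'stages'")
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s) {unknown}; known: {KNOWN_STAGES}")
    simulate_cfg = config.get("simulate", {})
    if "call-targets" in stages:
        has_counts = "counts" in config.get("call-targets", {})
        if not has_counts and not ("simulate" in stages and "ripseq" in simulate_cfg):
            raise ConfigurationError(
                "call-targets needs a 'counts' path or a simulate.ripseq stage"
            )
    for dep in ("overlap", "ora"):
        if dep in stages:
            blk = config.get(dep, {})
            if "targets" not in blk and "call-targets" not in stages:
                raise ConfigurationError(
                    f"{dep} needs a 'targets' gene-list path or a call-targets stage"
                )
    if "memory-test" in stages:
        blk = config.get("memory-test", {})
        if "bouts" not in blk and not (
            "simulate" in stages and "courtship" in simulate_cfg
        ):
            raise ConfigurationError(
                "memory-test needs a 'bouts' path or a simulate.courtship stage"
            )
    if "cpe-census" in stages:
        blk = config.get("cpe-census", {})
        if "fasta" not in blk and not ("simulate" in stages and "utr" in simulate_cfg):
            raise ConfigurationError(
                "cpe-census needs a 'fasta' path or a simulate.utr stage"
            )
    if "western-quant" in stages:
        blk = config.get("western-quant", {})
        if "densitometry" not in blk and not (
            "simulate" in stages and "western" in simulate_cfg
        ):
            raise ConfigurationError(
                "western-quant needs a 'densitometry' path or a simulate.western stage"
            )
    if "qpcr-quant" in stages and "ct" not in config.get("qpcr-quant", {}):
        raise ConfigurationError("qpcr-quant needs a 'ct' table path")
    return sorted(stages, key=_STAGE_ORDER.__getitem__)


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Validate, run the requested stages in dependency order, write outputs.

    Returns a report dict (also the content of ``manifest.json`` plus
    in-memory results).
    """
    stages = _validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict[str, Any] = {}
    outputs: dict[str, str] = {}

    counts: pd.DataFrame | None = None
    truth = None
    called: list[str] | None = None
    observations = None
    utr_records: dict[str, str] | None = None
    western_table: pd.DataFrame | None = None

    for stage in stages:
        params = dict(config.get(stage, {}))
        log.info("stage=%s seed=%s params=%s", stage, seed, params)

        if stage == "simulate":
            if "ripseq" in params:
                cfg = synth.RipSimConfig(seed=seed, **params["ripseq"])
                counts, truth = synth.simulate_ripseq(cfg)
                io.write_counts(counts, out / "counts.tsv")
                pd.DataFrame(
                    {"gene_id": sorted(truth.target_ids)}
                ).assign(role="target").pipe(
                    lambda df: pd.concat(
                        [
                            df,
                            pd.DataFrame(
                                {
                                    "gene_id": list(truth.control_ids.values()),
                                    "role": list(truth.control_ids.keys()),
                                }
                            ),
                        ]
                    )
                ).to_csv(out / "truth.tsv", sep="\t", index=False)
                outputs["counts"] = str(out / "counts.tsv")
                outputs["truth"] = str(out / "truth.tsv")
            if "courtship" in params:
                cfg = synth.BehaviorSimConfig(seed=seed, **params["courtship"])
                observations = synth.simulate_courtship(cfg)
                io.write_bouts(observations, out / "bouts.csv")
                outputs["bouts"] = str(out / "bouts.csv")
            if "western" in params:
                wparams = dict(params["western"])
                if "loads" in wparams:
                    wparams["loads"] = tuple(wparams["loads"])
                cfg = synth.WesternSimConfig(seed=seed, **wparams)
                western_table = synth.simulate_western(cfg)
                io.write_densitometry(western_table, out / "densitometry.csv")
                outputs["densitometry"] = str(out / "densitometry.csv")
            if "utr" in params:
                uparams = dict(params["utr"])
                if "planted" in uparams:
                    uparams["planted"] = tuple(
                        (str(m), int(c)) for m, c in uparams["planted"]
                    )
                cfg = synth.UtrSimConfig(seed=seed, **uparams)
                sequence, placements = synth.simulate_utr(cfg)
                utr_records = {"utr_1": sequence}
                io.write_fasta(utr_records, out / "utrs.fasta")
                outputs["utrs"] = str(out / "utrs.fasta")
                report["utr_planted"] = [[int(p), m] for p, m in placements]

        elif stage == "call-targets":
            if "counts" in params:
                counts = io.read_counts(params["counts"])
            assert counts is not None
            controls = tuple(params.get("controls", rip_enrichment.DEFAULT_CONTROLS))
            called, table, thresholds = rip_enrichment.call_targets_from_counts(
                counts,
                counts["biotype"],
                control_ids=controls,
                pseudocount=float(params.get("pseudocount", 0.5)),
                min_count=int(params.get("min_count", 1)),
            )
            io.write_enrichment(table, out / "enrichment.tsv")
            io.write_gene_list(called, out / "called_targets.txt")
            outputs["enrichment"] = str(out / "enrichment.tsv")
            outputs["called_targets"] = str(out / "called_targets.txt")
            report["call-targets"] = {
                "n_called": len(called),
                "thresholds": {
                    "min_ratio_ip_input": thresholds.min_ratio_ip_input,
                    "min_ratio_ip_mock": thresholds.min_ratio_ip_mock,
                },
            }

        elif stage == "overlap":
            if "targets" in params:
                called = io.read_gene_set(params["targets"])
            assert called is not None
            other = io.read_gene_set(params["other"])
            universe_ids = (
                io.read_gene_set(params["universe"])
                if "universe" in params
                else sorted(set(called) | set(other))
            )
            res = set_enrichment.overlap(
                set_enrichment.GeneSet.from_ids("targets", called),
                set_enrichment.GeneSet.from_ids("other", other),
                set_enrichment.GeneSet.from_ids("universe", universe_ids),
            )
            report["overlap"] = res.__dict__
        elif stage == "ora":
            if "targets" in params:
                called = io.read_gene_set(params["targets"])
            assert called is not None
            annotation = io.read_gmt(params["annotation"])
            universe_ids = (
                io.read_gene_set(params["universe"])
                if "universe" in params
                else sorted(set(called) | {g for gs in annotation.values() for g in gs})
            )
            results = set_enrichment.ora_fold_enrichment(
                set_enrichment.GeneSet.from_ids("targets", called),
                annotation,
                set_enrichment.GeneSet.from_ids("universe", universe_ids),
            )
            df = pd.DataFrame([r.__dict__ for r in results])
            df.to_csv(out / "ora.tsv", sep="\t", index=False)
            outputs["ora"] = str(out / "ora.tsv")
            report["ora"] = {"n_terms_tested": len(results)}

        elif stage == "memory-test":
            if "bouts" in params:
                observations = io.read_bouts(params["bouts"])
            assert observations is not None
            groups = sorted({o.group for o in observations})
            if len(groups) != 2:
                raise ConfigurationError(
                    f"memory-test needs exactly two groups, found {groups}"
                )
            cis = {
                g: [
                    behavior_stats.courtship_index(o)
                    for o in observations
                    if o.group == g
                ]
                for g in groups
            }
            res = behavior_stats.randomization_test(
                cis[groups[0]],
                cis[groups[1]],
                statistic=params.get("statistic", "mean-difference"),
                sides=params.get("sides", "two-sided"),
                n_permutations=int(params.get("n_perm", 10_000)),
                seed=seed,
            )
            alpha = float(params.get("alpha", 0.05))
            report["memory-test"] = {
                "groups": groups,
                "statistic_observed": res.statistic_observed,
                "alpha_R": res.alpha_R,
                "n_permutations": res.n_permutations,
                "reject_null": res.alpha_R < alpha,
            }

        elif stage == "cpe-census":
            if "fasta" in params:
                utr_records = io.read_fasta(params["fasta"])
            assert utr_records is not None
            motifs = (
                io.read_motifs_yaml(params["motifs"])
                if "motifs" in params
                else cpe_scan.DEFAULT_MOTIFS
            )
            deletion = params.get("deletion")
            censuses, hits = [], []
            for seq_id, seq in utr_records.items():
                if deletion:
                    start, end = (int(x) for x in str(deletion).split(":"))
                    seq = cpe_scan.apply_deletion(seq, (start, end))
                c = cpe_scan.census(seq, motifs, seq_id=seq_id)
                censuses.append(c)
                hits.extend(c.hits)
            io.write_census(censuses, out / "cpe_census.tsv")
            io.write_bed6(hits, out / "cpe_hits.bed")
            outputs["cpe_census"] = str(out / "cpe_census.tsv")
            outputs["cpe_hits"] = str(out / "cpe_hits.bed")
            report["cpe-census"] = {
                c.seq_id: {
                    "n_canonical": c.n_canonical,
                    "n_noncanonical": c.n_noncanonical,
                    "n_total": c.n_total,
                }
                for c in censuses
            }

        elif stage == "western-quant":
            if "densitometry" in params:
                series = io.read_densitometry(params["densitometry"])
            else:
                assert western_table is not None
                import tempfile

                with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
                    western_table.to_csv(fh.name, index=False)
                    series = io.read_densitometry(fh.name)
            genotypes = sorted({s.genotype for s in series})
            if len(genotypes) != 2:
                raise ConfigurationError(
                    f"western-quant needs exactly two genotypes, found {genotypes}"
                )
            mut_label = params.get("mut", "mut")
            mut = [s for s in series if s.genotype == mut_label]
            wt = [s for s in series if s.genotype != mut_label]
            res = quant.relative_level(mut, wt, test=params.get("test", "welch"))
            report["western-quant"] = {
                "ratio_mut_over_wt": res.ratio_mut_over_wt,
                "p_value": res.p_value,
                "n_mut": len(res.levels_mut),
                "n_wt": len(res.levels_wt),
            }

        elif stage == "qpcr-quant":
            table = io.read_ct(params["ct"])
            calibrator = params.get("calibrator", str(table["sample"].iloc[0]))
            rel = quant.relative_expression_ddct(table, calibrator)
            report["qpcr-quant"] = {
                "calibrator": calibrator,
                "relative_expression": rel.to_dict(),
            }

    manifest = {
        "package": "riplab",
        "version": _pkg_version("riplab"),
        "python": platform.python_version(),
        "seed": seed,
        "stages": stages,
        "parameters": {s: config.get(s, {}) for s in stages},
        "outputs": outputs,
        "report": report,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
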
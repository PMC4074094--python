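"""End-to-end orchestration of the prion network analysis.

``run_pipeline`` drives: curated/NQP set assembly -> interactome parse ->
interaction enrichment grids (whole-interactome and NQP-restricted
backgrounds) -> composite-set and hub/non-hub grids -> the GO triad
(membership, high-membership, interaction-based) -> cross-referencing ->
the Monte-Carlo disorder test -> annotated edge-list export.  Every
table is written as TSV into the output directory together with a run
log and a verbatim copy of the configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .bias import BiasThresholds, scan_proteome
from .datasets import (
    ProteinSet,
    derive_composite_sets,
    disorder_content,
    load_curated_sets,
    proteome_index,
    read_accession_list,
    read_disorder,
    read_fasta,
)
from .disorder import histogram_table, mc_disorder_test
from .enrichment import apply_holm, enrichment_grid, grid_tables
from .go import (
    cross_reference,
    high_membership_report,
    interaction_go_enrichment,
    membership_enrichment,
    read_annotations,
    read_ontology,
    term_results_frame,
)
from .hubs import find_hubs, partition_and_enrich
from .network import read_mitab, write_edge_list
from .reference import verify_printed_values

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _default_config() -> dict[str, Any]:
    return {
        "inputs": {},
        "alpha": 0.05,
        "hub_min_partners": 10,
        "disorder_threshold": 0.5,
        "mc_samples": 10000,
        "drop_marginal_kps": False,
        "seed": 0,
        "bias": {},
    }


def load_config(path: str | Path) -> dict[str, Any]:
    cfg = _default_config()
    cfg.update(yaml.safe_load(Path(path).read_text()) or {})
    return cfg


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute every stage; returns a summary dict (also written as YAML)."""
    cfg = _default_config()
    cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    inputs = cfg["inputs"]
    alpha = cfg["alpha"]
    summary: dict[str, Any] = {"version": __version__, "seed": cfg["seed"], "warnings": []}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # --- set assembly -----------------------------------------------------
    name = stage("sets")
    try:
        sets = load_curated_sets(drop_marginal_kps=cfg["drop_marginal_kps"])
        records = read_fasta(inputs["fasta"]) if "fasta" in inputs else []
        if "nqp" in inputs:
            sets["NQP"] = read_accession_list(inputs["nqp"], "NQP")
        elif records:
            thresholds = BiasThresholds(**cfg.get("bias", {}))
            sets["NQP"], bias_table = scan_proteome(records, thresholds=thresholds)
            bias_table.to_csv(out / "bias_scan.tsv", sep="\t", index=False)
        else:
            raise ValueError("need either an NQP list or a FASTA proteome to scan")
        pbd = (
            read_accession_list(inputs["pbd"], "PBD")
            if "pbd" in inputs
            else ProteinSet("PBD", set())
        )
        tracks = read_disorder(inputs["disorder"]) if "disorder" in inputs else {}
        composites = derive_composite_sets(
            sets["NQP"], pbd, tracks, cfg["disorder_threshold"]
        )
        summary["set_sizes"] = {n: len(s) for n, s in {**sets, **composites}.items()}
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise StageError(name, exc) from exc

    # --- interactome ------------------------------------------------------
    name = stage("interactome")
    try:
        net = read_mitab(inputs["mitab"]) if "mitab" in inputs else None
        if net is None or len(net) == 0:
            summary["warnings"].append("empty interaction network")
        summary["n_interactions"] = len(net) if net else 0
    except Exception as exc:
        raise StageError(name, exc) from exc

    grid_sets = [sets["KP"], sets["EPD"], sets["EPN"], sets["NQP"]]
    target_sets = grid_sets + [composites["disordered_not_NQP"]]

    # --- enrichment grids -------------------------------------------------
    name = stage("enrichment")
    try:
        if net is not None:
            results_whole = enrichment_grid(net, grid_sets, target_sets, alpha=alpha)
            wide, long = grid_tables(results_whole)
            wide.to_csv(out / "grid_whole_background.tsv", sep="\t")
            long.to_csv(out / "grid_whole_background_long.tsv", sep="\t", index=False)

            nqp_background = net.restricted_to(sets["NQP"])
            results_nqp_bg = enrichment_grid(
                net, grid_sets, [sets["NQP"]], background=nqp_background, alpha=alpha
            )
            _, long_bg = grid_tables(results_nqp_bg)
            long_bg.to_csv(out / "grid_nqp_background_long.tsv", sep="\t", index=False)
            summary["n_enrichment_tests"] = len(results_whole) + len(results_nqp_bg)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- hubs and partitions ----------------------------------------------
    name = stage("hubs")
    try:
        if net is not None:
            hub_records = find_hubs(
                net, sets["EPD"], sets["NQP"], cfg["hub_min_partners"]
            )
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "accession": h.accession,
                        "interactors": h.interactor_count,
                        "nqp_partners": h.partner_count,
                        "p_raw": h.p_raw,
                    }
                    for h in hub_records
                ],
                columns=["accession", "interactors", "nqp_partners", "p_raw"],
            ).to_csv(out / "hubs.tsv", sep="\t", index=False)
            partition_targets = [
                sets["NQP"],
                composites["PBD_not_NQP"],
                composites["NQP_not_PBD"],
                composites["NQP_and_PBD"],
                composites["disordered_not_NQP"],
            ]
            partitions = partition_and_enrich(
                net, sets["EPD"], [h.accession for h in hub_records], partition_targets
            )
            flat = partitions["hub"] + partitions["nonhub"]
            if flat:
                apply_holm(flat, alpha)
            _, part_long = grid_tables(flat)
            part_long.to_csv(out / "grid_hub_partition_long.tsv", sep="\t", index=False)
            summary["hubs"] = [h.accession for h in hub_records]
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- GO triad ---------------------------------------------------------
    name = stage("go")
    go_triad = None
    try:
        if "obo" in inputs and "gaf" in inputs:
            dag = read_ontology(inputs["obo"])
            annot = read_annotations(inputs["gaf"], dag)
            universe = [r.accession for r in records] if records else sorted(
                annot.propagated
            )
            membership = membership_enrichment(
                sets["NQP"], annot, universe, dag, alpha=alpha
            )
            term_results_frame(membership).to_csv(
                out / "go_membership.tsv", sep="\t", index=False
            )
            high = high_membership_report(membership, sets["NQP"], annot, dag, universe)
            import pandas as pd

            pd.DataFrame(
                {
                    "yeast_count": h.yeast_count,
                    "set_count": h.set_count,
                    "fraction": h.fraction,
                    "term": h.term,
                    "name": h.name,
                    "p_raw": h.p_raw,
                    "passes_correction": h.passes_correction,
                }
                for h in high
            ).to_csv(out / "go_high_membership.tsv", sep="\t", index=False)
            interaction = (
                interaction_go_enrichment(net, sets["NQP"], annot, dag, alpha=alpha)
                if net is not None
                else []
            )
            term_results_frame(interaction).to_csv(
                out / "go_interaction.tsv", sep="\t", index=False
            )
            # third leg of the triad: GO enrichment of the hubs' NQP partners
            hub_partner_results = []
            if net is not None and summary.get("hubs"):
                partners: set[str] = set()
                for hub in summary["hubs"]:
                    partners |= net.interactors(hub) & sets["NQP"].members
                if partners:
                    hub_partner_results = membership_enrichment(
                        ProteinSet("hub_NQP_partners", partners),
                        annot,
                        universe,
                        dag,
                        alpha=alpha,
                    )
                    term_results_frame(hub_partner_results).to_csv(
                        out / "go_hub_partners.tsv", sep="\t", index=False
                    )
            high_terms = {h.term for h in high if h.passes_correction}
            membership_high = [r for r in membership if r.term in high_terms]
            triad = cross_reference(membership_high, interaction, hub_partner_results)
            go_triad = sorted(triad)
            (out / "go_cross_reference.txt").write_text(
                "".join(f"{t}\n" for t in go_triad)
            )
            summary["go_triad"] = go_triad
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- Monte-Carlo disorder test ----------------------------------------
    name = stage("disorder_mc")
    try:
        if tracks:
            mc_rows = []
            for set_name in ("KP", "EPD", "EPN"):
                pset = sets[set_name]
                have = pset.members & set(tracks)
                if not have:
                    continue
                pset = ProteinSet(set_name, have)
                result = mc_disorder_test(
                    pset, tracks, n_samples=cfg["mc_samples"], seed=cfg["seed"]
                )
                disordered, total, fraction = disorder_content(pset, tracks)
                mc_rows.append(
                    {
                        "set": set_name,
                        "observed_disordered": result.observed,
                        "total_residues": total,
                        "fraction": fraction,
                        "exceed_fraction": result.exceed_fraction,
                        "n_samples": result.n_samples,
                    }
                )
                histogram_table(result).to_csv(
                    out / f"mc_disorder_hist_{set_name}.tsv", sep="\t", index=False
                )
            if mc_rows:
                import pandas as pd

                pd.DataFrame(mc_rows).to_csv(
                    out / "mc_disorder.tsv", sep="\t", index=False
                )
                summary["mc_exceed_fractions"] = {
                    r["set"]: r["exceed_fraction"] for r in mc_rows
                }
    except Exception as exc:
        raise StageError(name, exc) from exc

    # --- network export ---------------------------------------------------
    name = stage("export")
    try:
        if net is not None:
            epd_net = net.restricted_to(sets["EPD"])
            write_edge_list(epd_net, out / "epd_edge_list.tsv", sets)
    except Exception as exc:
        raise StageError(name, exc) from exc

    (out / "run_log.yaml").write_text(yaml.safe_dump(summary, sort_keys=True))
    return summary


def write_verification(out_path: str | Path) -> "pandas.DataFrame":
    """Recompute the published P-values and emit the pass/fail table."""
    table = verify_printed_values()
    table.to_csv(out_path, sep="\t", index=False)
    return table
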
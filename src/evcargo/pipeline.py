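"""End-to-end analysis pipeline over a cohort dataset.

Composes the stages in the study's order: responder/non-responder DE at
diagnosis and at end of chemotherapy, two-timepoint candidate intersection,
healthy-control specificity filter, ROC/Youden evaluation, chemo-induced RNA
selection, and cohort statistics.  All outputs are deterministic TSV/JSON
with a checksum manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .assign import biotype_proportions
from .de import Contrast, run_de
from .discover import (evaluate_candidates, hc_specificity_filter,
                       nac_induced_select, select_candidates)
from .matrix import CountMatrix
from .simulate import CohortDataset
from .stats import characteristics_table, kruskal_wallis, wilcoxon_rank_sum

log = logging.getLogger("evcargo")


@dataclass
class PipelineThresholds:
    lfc: float = 1.0
    alpha: float = 0.05
    detect_tau: float = 1.0
    max_hc_fraction: float = 0.0
    min_read_length: int = 15
    hc_filter_mode: str = "de"


@dataclass
class PipelineResult:
    de_tables: dict
    candidates: pd.DataFrame
    nac_induced: dict
    stats_report: dict
    outputs: dict = field(default_factory=dict)


def _ids(samples: pd.DataFrame, group=None, timepoint=None) -> list:
    mask = pd.Series(True, index=samples.index)
    if group is not None:
        groups = [group] if isinstance(group, str) else list(group)
        mask &= samples["group"].isin(groups)
    if timepoint is not None:
        mask &= samples["timepoint"] == timepoint
    return samples.loc[mask, "sample_id"].tolist()


def run_pipeline(samples: pd.DataFrame, cm: CountMatrix,
                 particles: pd.DataFrame | None = None,
                 thresholds: PipelineThresholds | None = None,
                 outdir=None, seed: int = 0,
                 config_dict: dict | None = None) -> PipelineResult:
    """Run the full discovery workflow on one cohort.

    Stages are logged with feature counts in and out; when ``outdir`` is
    given, every artifact is written as TSV/JSON plus a manifest with the
    seed and per-file checksums.
    """
    th = thresholds or PipelineThresholds()
    hc = _ids(samples, group="HC")
    nr_dg = _ids(samples, group="NR", timepoint="Dg")
    r_dg = _ids(samples, group="R", timepoint="Dg")
    nr_nac = _ids(samples, group="NR", timepoint="NAC")
    r_nac = _ids(samples, group="R", timepoint="NAC")
    bc_dg = _ids(samples, group=("R", "NR"), timepoint="Dg")
    bc_nac = _ids(samples, group=("R", "NR"), timepoint="NAC")

    subj = samples.drop_duplicates("subject_id")
    prog = subj.loc[subj["progression_18m"] == "yes", "subject_id"] \
        if "progression_18m" in subj.columns else pd.Series(dtype=str)
    p_nac = [s for s in bc_nac
             if s.rsplit("_", 1)[0] in set(prog)]
    np_nac = [s for s in bc_nac if s not in set(p_nac)]

    de_tables = {}

    def _de(a, b, label):
        res = run_de(cm, Contrast(a, b, label=label),
                     lfc_threshold=th.lfc, alpha=th.alpha)
        de_tables[label] = res
        log.info("DE %s: %d features, %d up in a, %d up in b", label,
                 len(res.table), res.table["up_in_a"].sum(),
                 res.table["up_in_b"].sum())
        return res

    de_dg = _de(nr_dg, r_dg, "NRvsR@Dg")
    de_nac = _de(nr_nac, r_nac, "NRvsR@NAC")

    candidates = select_candidates(de_dg, de_nac)
    log.info("two-timepoint candidates: %d", len(candidates))
    candidates = hc_specificity_filter(
        candidates, cm, hc, nr_dg, mode=th.hc_filter_mode,
        tau=th.detect_tau, max_hc_fraction=th.max_hc_fraction,
        lfc_threshold=th.lfc, alpha=th.alpha)
    log.info("after HC specificity filter: %d", len(candidates))
    candidates = evaluate_candidates(candidates, cm, nr_dg, r_dg)

    de_nac_vs_dg = _de(bc_nac, bc_dg, "NACvsDg")
    de_nac_vs_hc = _de(bc_nac, hc, "NACvsHC")
    if p_nac and np_nac:
        de_p_vs_np = _de(p_nac, np_nac, "PvsNP@NAC")
        nac_induced = nac_induced_select(de_nac_vs_dg, de_nac_vs_hc,
                                         de_nac, de_p_vs_np)
    else:
        nac_induced = nac_induced_select(de_nac_vs_dg, de_nac_vs_hc,
                                         de_nac, de_nac)
        nac_induced["progression"] = []
        nac_induced["common"] = []

    stats_report = {"characteristics": characteristics_table(samples)}
    if particles is not None:
        conc = particles.set_index("sample_id")["concentration"]
        by = {(g, t): conc.loc[_ids(samples, g, t)].to_numpy()
              for g in ("HC", "R", "NR")
              for t in samples.loc[samples["group"] == g, "timepoint"].unique()}
        comparisons = {}
        hc_c = by.get(("HC", "HC"))
        for key, label in ((("NR", "Dg"), "HCvsNR@Dg"),
                           (("R", "Dg"), "HCvsR@Dg"),
                           (("NR", "PostOp6m"), "HCvsNR@PostOp6m")):
            if hc_c is not None and key in by and len(by[key]):
                _, p = wilcoxon_rank_sum(hc_c, by[key])
                comparisons[label] = p
        for g in ("R", "NR"):
            if ("%s" % g, "Dg") in by and (g, "NAC") in by:
                _, p = wilcoxon_rank_sum(by[(g, "Dg")], by[(g, "NAC")])
                comparisons[f"DgvsNAC@{g}"] = p
        stats_report["particle_wilcoxon"] = comparisons

    props = biotype_proportions(cm)
    kw = {}
    tp_of = samples.set_index("sample_id")["timepoint"]
    for bt in props.columns:
        groups = [props.loc[tp_of == tp, bt].to_numpy()
                  for tp in tp_of.unique()]
        groups = [g for g in groups if len(g)]
        if len(groups) >= 2:
            _, _, p = kruskal_wallis(*groups)
            kw[bt] = p
    stats_report["biotype_kruskal_wallis"] = kw

    result = PipelineResult(de_tables=de_tables, candidates=candidates,
                            nac_induced=nac_induced,
                            stats_report=stats_report)
    if outdir is not None:
        result.outputs = _write_outputs(result, samples, outdir, seed,
                                        config_dict or {})
    return result


def _write_outputs(result: PipelineResult, samples: pd.DataFrame,
                   outdir, seed: int, config_dict: dict) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    for label, de in result.de_tables.items():
        p = outdir / f"de_{label.replace('@', '_at_')}.tsv"
        de.table.sort_index().to_csv(p, sep="\t", index_label="feature_id")
        outputs[f"de_{label}"] = p
    p = outdir / "candidates.tsv"
    result.candidates.sort_index().to_csv(p, sep="\t",
                                          index_label="feature_id")
    outputs["candidates"] = p
    p = outdir / "nac_induced.json"
    with open(p, "w") as fh:
        json.dump(result.nac_induced, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["nac_induced"] = p
    p = outdir / "stats_report.json"
    report = {k: (v.to_dict(orient="records")
                  if isinstance(v, pd.DataFrame) else v)
              for k, v in result.stats_report.items()}
    with open(p, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["stats_report"] = p
    io.write_manifest(outputs, seed, config_dict, outdir / "manifest.json")
    outputs["manifest"] = outdir / "manifest.json"
    return outputs
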
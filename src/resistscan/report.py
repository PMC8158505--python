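"""End-to-end orchestration: screen -> F_ST/null -> CNV burden -> power,
collected into one versioned JSON run report.

The report echoes the full configuration (seed included) so a rerun with
the echoed config reproduces every number; a failure in one stage is
recorded in that stage's status and does not silently skip the others.
Raw exact-test p-values are reported without multiple-testing correction,
alongside the number of tests performed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, catalog_io
from .burden import burden, burden_contrast
from .consequence import cohort_contrast, screen
from .fst import labels_from_popmap, resampling_null
from .power import miss_probability, min_sample_size

log = logging.getLogger(__name__)

REPORT_SCHEMA = "resistscan-report-v1"


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _stage(report: dict, name: str, fn) -> None:
    try:
        out = fn()
        report["stages"][name] = {"status": "ok", **out}
    except Exception as exc:  # recorded, not swallowed silently
        log.error("stage %s failed: %s", name, exc)
        report["stages"][name] = {
            "status": "failed", "error": f"{type(exc).__name__}: {exc}",
            "traceback": traceback.format_exc(limit=3)}


def run_all(config: dict, out_dir: Optional[str | Path] = None) -> dict:
    """Run every configured stage; returns (and optionally writes) the
    report dict.  Config keys (all optional except where a stage needs
    them): vcf, popmap, catalog, genes, cds, cnv, clans,
    fst {chrom,start,end,groups,level,n_reps,seed,genome_extent},
    power [{p,n} | {p,alpha}].
    """
    _validate_config(config)
    report: dict = {"schema": REPORT_SCHEMA, "version": __version__,
                    "config": config,
                    "input_hashes": {}, "stages": {}, "warnings": [],
                    "n_exact_tests": 0}
    for key in ("vcf", "popmap", "catalog", "genes", "cds", "cnv", "clans"):
        if config.get(key):
            report["input_hashes"][key] = _file_hash(config[key])

    gm = popmap = None
    if config.get("vcf"):
        gm = catalog_io.read_vcf(config["vcf"])
    if config.get("popmap"):
        popmap = catalog_io.read_popmap(config["popmap"])

    if gm is not None and popmap is not None and config.get("catalog"):
        def _screen():
            models = (catalog_io.read_gene_models(config["genes"])
                      if config.get("genes") else {})
            cds = (catalog_io.read_cds_fasta(config["cds"])
                   if config.get("cds") else {})
            catalog = catalog_io.read_catalog(config["catalog"],
                                              models or None)
            res = screen(gm, catalog, models, popmap, cds)
            block: dict = {"per_cohort": res.per_cohort.to_dict("records"),
                           "per_population":
                               res.per_population.to_dict("records"),
                           "skipped_mutations": res.skipped_mutations,
                           "carriers": {m.mutation_id:
                                        res.carriers(m.mutation_id)
                                        for m in catalog}}
            contrasts = {}
            cohorts = set(res.per_cohort["group"])
            if len(cohorts) == 2:
                for m in catalog:
                    table, p, _ = cohort_contrast(res, m.mutation_id)
                    contrasts[m.mutation_id] = {
                        "table": table.tolist(), "p": p}
                    report["n_exact_tests"] += 1
            block["cohort_contrasts"] = contrasts
            return block
        _stage(report, "screening", _screen)

    if gm is not None and popmap is not None and config.get("fst"):
        def _fst():
            f = config["fst"]
            labels = labels_from_popmap(gm, popmap, f.get("level", "cohort"),
                                        *f["groups"])
            null = resampling_null(
                gm, labels, (f["chrom"], int(f["start"]), int(f["end"])),
                f.get("genome_extent") or _extent_from_vcf(config["vcf"]),
                int(f.get("n_reps", 1000)), int(f.get("seed", 0)))
            return {"null": null.summary()}
        _stage(report, "fst_null", _fst)

    if popmap is not None and config.get("cnv") and config.get("clans"):
        def _burden():
            cnv = catalog_io.read_cnv_table(config["cnv"], config["clans"])
            summ = burden(cnv, popmap)
            tests = {}
            if len(summ.cohorts) == 2:
                for clan in summ.clans:
                    table, p = burden_contrast(summ, clan)
                    tests[clan] = {"table": table.tolist(), "p": p}
                    report["n_exact_tests"] += 1
            return {"summary": summ.table.to_dict("records"),
                    "contrasts": tests}
        _stage(report, "cnv_burden", _burden)

    if config.get("power"):
        def _power():
            out = []
            for q in config["power"]:
                entry = {"p": q["p"]}
                if "n" in q:
                    entry["n"] = q["n"]
                    entry["miss_probability"] = miss_probability(
                        q["p"], int(q["n"]))
                if "alpha" in q:
                    entry["alpha"] = q["alpha"]
                    entry["min_sample_size"] = min_sample_size(
                        q["p"], q["alpha"])
                out.append(entry)
            return {"queries": out}
        _stage(report, "power", _power)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1,
                                                    default=_jsonable))
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _extent_from_vcf(path: str) -> dict[str, int]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    extent = dict(zip(vcf.seqnames, vcf.seqlens))
    vcf.close()
    if not extent:
        raise ValueError("VCF header lacks contig lengths; pass "
                         "fst.genome_extent explicitly")
    return extent


def _validate_config(config: dict) -> None:
    known = {"vcf", "popmap", "catalog", "genes", "cds", "cnv", "clans",
             "fst", "power"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("vcf", "popmap", "catalog", "genes", "cds", "cnv", "clans"):
        if config.get(key) and not Path(config[key]).exists():
            raise FileNotFoundError(f"config.{key}: {config[key]} not found")
    if config.get("fst"):
        need = {"chrom", "start", "end", "groups"} - set(config["fst"])
        if need:
            raise ValueError(f"config.fst missing {sorted(need)}")
    for q in config.get("power", []):
        if "p" not in q or ("n" not in q and "alpha" not in q):
            raise ValueError("each power query needs p and one of n/alpha")
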
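"""End-to-end orchestration: filter -> burden/MSI -> kataegis ->
signatures -> chromothripsis -> features -> clustering -> enrichment.

The pipeline is pure dataflow between per-sample input files and per-run
output tables; no stage mutates another stage's inputs. Every output
table carries the tool version and a hash of the effective configuration
as '#' comment lines, and the effective configuration itself is written
next to the outputs.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import MutationCounts, classify_msi, tmb
from .chromothripsis import ChromothripsisCriteria, call_chromothripsis
from .clustering import cluster, cluster_enrichment
from .core import GenomeSpec, SampleData
from .features import SIZE_CUT_BP, build_feature_matrix
from .filters import FilterThresholds, apply_heuristic_filters, filter_svs_by_baf
from .io import read_cn_segments, read_svs, read_variants, write_table
from .kataegis import call_kataegis
from .signatures import build_spectrum, fit_signatures
from .simulate import default_catalog

log = logging.getLogger("scarscape")


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    genome: str = "mini"                 # "mini", "grch37", or a name map
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    chromothripsis: ChromothripsisCriteria = field(
        default_factory=ChromothripsisCriteria)
    msi_threshold: int = 11_436
    size_cut: int = SIZE_CUT_BP
    k: Optional[int] = None              # None -> elbow selection
    n_boot: int = 200
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filters = FilterThresholds(**raw.pop("filters", {}))
        ct = ChromothripsisCriteria(**raw.pop("chromothripsis", {}))
        return cls(filters=filters, chromothripsis=ct, **raw)


def _resolve_genome(name: str) -> GenomeSpec:
    if name == "mini":
        return GenomeSpec.mini()
    if name == "grch37":
        return GenomeSpec.grch37()
    raise ValueError(f"unknown genome {name!r}")


def _load_sample(input_dir: Path, sample_id: str) -> SampleData:
    vpath = input_dir / f"{sample_id}.variants.tsv"
    spath = input_dir / f"{sample_id}.seg"
    bpath = input_dir / f"{sample_id}.bedpe"
    for p in (vpath, spath, bpath):
        if not p.exists():
            raise FileNotFoundError(
                f"missing input {p.name} for sample {sample_id}")
    return SampleData(
        sample_id=sample_id,
        variants=read_variants(vpath),
        svs=read_svs(bpath),
        segments=read_cn_segments(spath),
    )


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run every stage over the cohort in ``config.input_dir``.

    Sample ids are taken from the cohort metadata table. Any stage error
    aborts the run naming the stage and the offending sample. Returns the
    result tables, which are also written to ``config.output_dir``.
    """
    input_dir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = _resolve_genome(config.genome)
    provenance = [f"scarscape {__version__}",
                  f"config {config.config_hash()}"]
    with open(outdir / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    metadata = pd.read_csv(input_dir / "cohort_metadata.tsv", sep="\t")
    sample_ids = list(metadata["sample_id"])
    catalog = default_catalog()

    filter_rows, burden_rows, msi_rows = [], [], []
    kataegis_rows, signature_rows, ct_rows = [], [], []
    samples_for_features: list[SampleData] = []
    stage = "load"
    t0 = time.time()
    for sid in sample_ids:
        try:
            stage = "load"
            sample = _load_sample(input_dir, sid)

            stage = "filter"
            retained, report = apply_heuristic_filters(sample.variants,
                                                       config.filters)
            sample.variants = retained
            sample.svs = filter_svs_by_baf(sample.svs, config.filters)
            filter_rows.append({"sample_id": sid, **report})

            stage = "burden"
            counts = MutationCounts.from_variants(sample.variants)
            burden_rows.append({
                "sample_id": sid,
                "snv_g": counts.snv_g, "indel_g": counts.indel_g,
                "mnv_g": counts.mnv_g,
                "tmb_genomic": tmb(counts, genome, "genomic"),
                "tmb_coding": tmb(counts, genome, "coding"),
            })
            msi = classify_msi(sample.variants, config.msi_threshold)
            msi_rows.append({"sample_id": sid,
                             "qualifying_indels": msi.qualifying_indels,
                             "is_msi": msi.is_msi})

            stage = "kataegis"
            kat = call_kataegis(sample)
            kataegis_rows.append({
                "sample_id": sid, "n_events": len(kat.events),
                "hypermutator_reset": kat.hypermutator_reset,
            })

            stage = "signatures"
            fit = fit_signatures(build_spectrum(sample.variants), catalog)
            row = {"sample_id": sid, "residual_norm": fit.residual_norm}
            rel = (fit.relative_contributions
                   if fit.relative_contributions is not None
                   else np.zeros(len(fit.names)))
            row.update({name: float(c) for name, c in zip(fit.names, rel)})
            signature_rows.append(row)

            stage = "chromothripsis"
            events = call_chromothripsis(sample, genome, config.chromothripsis,
                                         seed=config.seed)
            ct_rows.append({
                "sample_id": sid,
                "n_passed": sum(e.passed for e in events),
                "chromothripsis": any(e.passed for e in events),
            })

            stage = "features"
            samples_for_features.append(sample)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed for sample {sid}: {exc}"
            ) from exc
        log.info("sample %s done (%.1fs elapsed)", sid, time.time() - t0)

    stage = "features"
    features = build_feature_matrix(samples_for_features, genome,
                                    size_cut=config.size_cut)

    stage = "cluster"
    result = cluster(features, k=config.k, n_boot=config.n_boot,
                     seed=config.seed)
    labels = result.labels

    stage = "enrichment"
    traits = _trait_table(samples_for_features, ct_rows)
    enrichment = cluster_enrichment(labels, traits)

    tables = {
        "filter_report": pd.DataFrame(filter_rows),
        "burden": pd.DataFrame(burden_rows),
        "msi": pd.DataFrame(msi_rows),
        "kataegis": pd.DataFrame(kataegis_rows),
        "signatures": pd.DataFrame(signature_rows),
        "chromothripsis": pd.DataFrame(ct_rows),
        "features": features.reset_index(),
        "clusters": pd.DataFrame({"sample_id": labels.index,
                                  "cluster": labels.to_numpy()}),
        "enrichment": enrichment,
    }
    for name, df in tables.items():
        write_table(df, outdir / f"{name}.tsv", provenance)
    wss = result.wss
    write_table(wss, outdir / "wss_curve.tsv", provenance)
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return tables


def _trait_table(samples: list[SampleData], ct_rows) -> pd.DataFrame:
    """Binary trait table for enrichment: per-gene aberration flags (from
    the annotated coding variants) plus chromothripsis presence."""
    genes = sorted({v.gene for s in samples for v in s.variants
                    if v.gene is not None})
    ct_map = {r["sample_id"]: bool(r["chromothripsis"]) for r in ct_rows}
    rows = {}
    for s in samples:
        flags = {g: False for g in genes}
        for v in s.variants:
            if v.gene in flags:
                flags[v.gene] = True
        flags["chromothripsis"] = ct_map.get(s.sample_id, False)
        rows[s.sample_id] = flags
    return pd.DataFrame.from_dict(rows, orient="index")
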
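"""Config-driven end-to-end runs: CU tables, fingerprints, zero-codon tables,
differential codon prioritization and mutation mapping.

A run consumes either file inputs (CDS FASTA + metadata TSV, optional
variant TSV) or a synthetic cohort spec, executes every analysis stage, and
writes plain-text outputs plus a JSON manifest.  Manifests are byte-identical
for identical config and seed (no timestamps), which is the pipeline's
reproducibility contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .genetic_code import build_genetic_code
from .mapping import cu_mutation_correlation, map_variants, mutation_burden
from .profiles import (
    count_codons,
    cu_long_table,
    cu_values,
    pool_cohort_counts,
    profiles_from_records,
    stop_codon_usage,
    zero_codons,
)
from .sequence_io import (
    CdsRecord,
    read_cds_fasta,
    read_variant_table,
    select_longest_isoform,
    write_cds_fasta,
    write_variant_table,
)
from .simulate import (
    CohortSpec,
    generate_cohort,
    generate_fingerprint_pair,
    write_ground_truth,
)
from .stats import (
    build_matrix,
    complete_linkage,
    euclidean_distance,
    most_differential_codons,
    to_newick,
    zero_codon_table,
)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; exactly one input mode is set."""

    # file mode
    fasta: Optional[str] = None
    metadata: Optional[str] = None
    variants: Optional[str] = None
    # synthetic mode
    synthetic: Optional[Dict] = None  # CohortSpec kwargs (+ "pair"/"concentration")
    # analysis toggles
    matrix: str = "per-gene"  # per-gene | pooled (pool by species+tissue+cohort)
    zero_policy: str = "family_present"
    cutoffs: Optional[Dict[int, float]] = None
    group_by: str = "cohort"  # cohort | tissue | species
    comparisons: Optional[List[Tuple[str, str]]] = None
    alpha: float = 0.05
    bh: bool = False
    longest_isoform: bool = True
    # run control
    out_dir: str = "cubkit_run"
    seed: int = 0

    def validate(self) -> "RunConfig":
        file_mode = self.fasta is not None
        synth_mode = self.synthetic is not None
        if file_mode == synth_mode:
            raise ValueError("set exactly one of file input (fasta) or synthetic mode")
        if file_mode and self.metadata is None:
            raise ValueError("file mode needs both fasta and metadata paths")
        if self.matrix not in ("per-gene", "pooled"):
            raise ValueError(f"unknown matrix mode {self.matrix!r}")
        return self


def load_config(path) -> RunConfig:
    """Load a YAML run config."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "cutoffs" in raw and raw["cutoffs"] is not None:
        raw["cutoffs"] = {int(k): float(v) for k, v in raw["cutoffs"].items()}
    if "comparisons" in raw and raw["comparisons"] is not None:
        raw["comparisons"] = [tuple(pair) for pair in raw["comparisons"]]
    return RunConfig(**raw).validate()


def _load_records(config: RunConfig, out: Path) -> List[CdsRecord]:
    if config.fasta is not None:
        records = read_cds_fasta(config.fasta, config.metadata)
        if config.longest_isoform:
            records = select_longest_isoform(records)
        return records
    synth = dict(config.synthetic or {})
    pair = bool(synth.pop("pair", False))
    concentration = float(synth.pop("concentration", 0.9))
    synth.setdefault("seed", config.seed)
    if "length_range" in synth:
        synth["length_range"] = tuple(synth["length_range"])
    if "injected_zero_codons" in synth:
        synth["injected_zero_codons"] = set(synth["injected_zero_codons"])
    spec = CohortSpec(**synth)
    if pair:
        low, high, gt_low, gt_high = generate_fingerprint_pair(
            spec, concentration=concentration
        )
        for rec in low:
            rec.cohort = "DC"
        for rec in high:
            rec.cohort = "NDC"
        records = low + high
        write_ground_truth(gt_low, out / "ground_truth_low.json")
        write_ground_truth(gt_high, out / "ground_truth_high.json")
    else:
        records, truth = generate_cohort(spec)
        write_ground_truth(truth, out / "ground_truth.json")
    write_cds_fasta(records, out / "synthetic.fasta", out / "synthetic_metadata.tsv")
    return records


def _cohort_key(rec: CdsRecord) -> Tuple[str, str, str]:
    return (rec.species, rec.tissue, rec.cohort)


def run_pipeline(config: RunConfig) -> Dict:
    """Execute every analysis stage and return the (also written) manifest."""
    config.validate()
    code = build_genetic_code()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "tool": "cubkit",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, n_records: int) -> None:
        manifest["stages"][name] = {"records": n_records}
        manifest["outputs"].append(name)

    records = _load_records(config, out)
    if not records:
        raise ValueError("no valid CDS records to analyze")
    manifest["stages"]["input"] = {"records": len(records)}

    # per-gene CU long table
    table = cu_long_table(
        records, code, zero_policy=config.zero_policy, cutoffs=config.cutoffs
    )
    table.to_csv(out / "cu_values.tsv", sep="\t", index=False)
    emit("cu_values.tsv", len(table))

    # stop-codon usage per cohort
    stop_rows = []
    cohorts: Dict[Tuple[str, str, str], List[CdsRecord]] = {}
    for rec in records:
        cohorts.setdefault(_cohort_key(rec), []).append(rec)
    for key in sorted(cohorts):
        usage = stop_codon_usage(cohorts[key])
        for stop, freq in sorted(usage.items()):
            stop_rows.append(
                {
                    "species": key[0],
                    "tissue": key[1],
                    "cohort": key[2],
                    "stop_codon": stop,
                    "frequency": freq,
                }
            )
    pd.DataFrame(stop_rows).to_csv(out / "stop_usage.tsv", sep="\t", index=False)
    emit("stop_usage.tsv", len(stop_rows))

    # fingerprint matrix + clustering
    if config.matrix == "per-gene":
        profiles = profiles_from_records(records, code)
    else:
        profiles = []
        for key in sorted(cohorts):
            pooled = pool_cohort_counts(
                [count_codons(r) for r in cohorts[key]], label="|".join(key)
            )
            profiles.append(cu_values(pooled, code))
    matrix = build_matrix(
        profiles,
        ordering="exon_count" if config.matrix == "per-gene" else "given",
        code=code,
    )
    matrix.to_frame().to_csv(out / "cu_matrix.tsv", sep="\t")
    emit("cu_matrix.tsv", len(matrix.row_ids))
    for axis, labels in (("rows", matrix.row_ids), ("cols", matrix.col_ids)):
        if len(labels) < 2:
            continue
        clust = complete_linkage(euclidean_distance(matrix, axis), labels, axis)
        name = f"dendrogram_{axis}.nwk"
        (out / name).write_text(to_newick(clust) + "\n", encoding="utf-8")
        emit(name, len(labels))

    # zero-codon reports and cohort table
    reports = {
        key: [
            zero_codons(count_codons(r), code, policy=config.zero_policy)
            for r in cohorts[key]
        ]
        for key in sorted(cohorts)
    }
    zc_rows = []
    per_gene_sum = zero_codon_table(reports)
    for key in sorted(cohorts):
        pooled = pool_cohort_counts([count_codons(r) for r in cohorts[key]])
        pooled_report = zero_codons(pooled, code, policy=config.zero_policy)
        zc_rows.append(
            {
                "species": key[0],
                "tissue": key[1],
                "cohort": key[2],
                "zero_codons_per_gene_sum": per_gene_sum[key],
                "zero_codons_pooled": pooled_report.count,
            }
        )
    pd.DataFrame(zc_rows).to_csv(out / "zero_codon_table.tsv", sep="\t", index=False)
    emit("zero_codon_table.tsv", len(zc_rows))
    gene_zc = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_zero_codons": rep.count,
                "zero_codons": ",".join(sorted(rep.zero_codons)),
            }
            for key in sorted(cohorts)
            for r, rep in zip(cohorts[key], reports[key])
        ]
    )
    gene_zc.to_csv(out / "zero_codons_per_gene.tsv", sep="\t", index=False)
    emit("zero_codons_per_gene.tsv", len(gene_zc))

    # differential codon usage between groups
    gene_profiles = profiles_from_records(records, code)
    groups: Dict[str, List] = {}
    for rec, prof in zip(records, gene_profiles):
        groups.setdefault(getattr(rec, config.group_by), []).append(prof)
    prioritized: List[str] = []
    if len(groups) >= 2:
        prioritized, diff_table = most_differential_codons(
            groups,
            comparisons=config.comparisons,
            alpha=config.alpha,
            method="bh" if config.bh else "raw",
            code=code,
        )
        diff_table.to_csv(out / "differential.tsv", sep="\t", index=False)
        emit("differential.tsv", len(diff_table))
        (out / "prioritized_codons.txt").write_text(
            "\n".join(prioritized) + ("\n" if prioritized else ""), encoding="utf-8"
        )
        emit("prioritized_codons.txt", len(prioritized))

    # mutation mapping-on-codons
    if config.variants is not None:
        variants = read_variant_table(config.variants)
        by_gene = {rec.gene_id: rec for rec in records}
        burden_frames = []
        exclusion_rows = []
        rho_rows = []
        for gene_id in sorted({v.gene_id for v in variants}):
            if gene_id not in by_gene:
                exclusion_rows.append(
                    {"gene_id": gene_id, "cds_pos": "", "reason": "unknown_gene"}
                )
                continue
            rec = by_gene[gene_id]
            mut_map = map_variants(
                rec, [v for v in variants if v.gene_id == gene_id], code
            )
            profile = cu_values(count_codons(rec), code)
            burden = mutation_burden(mut_map, profile, code, rec=rec)
            burden.insert(0, "gene_id", gene_id)
            burden_frames.append(burden)
            corr = cu_mutation_correlation(burden)
            rho_rows.append(
                {
                    "gene_id": gene_id,
                    "spearman_rho_cu_vs_rate": corr.rho,
                    "p_value": corr.p_value if corr.ok else "",
                }
            )
            for var, reason in mut_map.excluded:
                exclusion_rows.append(
                    {"gene_id": gene_id, "cds_pos": var.cds_pos, "reason": reason}
                )
        if burden_frames:
            pd.concat(burden_frames, ignore_index=True).to_csv(
                out / "mutation_burden.tsv", sep="\t", index=False
            )
            emit("mutation_burden.tsv", sum(len(f) for f in burden_frames))
            pd.DataFrame(rho_rows).to_csv(
                out / "mutation_cu_correlation.tsv", sep="\t", index=False
            )
            emit("mutation_cu_correlation.tsv", len(rho_rows))
        pd.DataFrame(
            exclusion_rows, columns=["gene_id", "cds_pos", "reason"]
        ).to_csv(out / "mutation_exclusions.tsv", sep="\t", index=False)
        emit("mutation_exclusions.tsv", len(exclusion_rows))

    manifest["prioritized_codons"] = prioritized
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
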
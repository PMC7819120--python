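"""One-shot orchestration: filter -> indices -> RSCU -> optimal codons ->
ordination -> PR2/ENC/neutrality, each stage written as a TSV.

Every number in the report files is produced by the stage APIs; the pipeline
only arranges and serializes.  Re-running with an unchanged config and input
produces byte-identical output files (no timestamps, fixed column order,
fixed float formatting).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .codon_model import standard_table, fourfold_pr2_families
from .cds_io import annotate_qc, read_sequences, write_filter_report
from .metrics import (
    count_codons,
    gene_indices,
    indices_frame,
    pool_counts,
    round_half_up,
    rscu,
    usage_frame,
)
from .expression import (
    call_optimal_codons,
    delta_rscu,
    high_frequency_codons,
    select_expression_sets,
)
from .multivariate import (
    RscuMatrix,
    build_rscu_matrix,
    correlate_indices,
    correlation_frame,
    correspondence_analysis,
    pca,
)
from .selection import (
    enc_plot,
    enc_plot_summary,
    neutrality_fit,
    pr2_family,
    pr2_gene,
    pr2_weighted_mean,
)

log = logging.getLogger("codonbias")

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline knobs with their analysis defaults."""

    input_path: str
    output_dir: str
    input_format: str = "fasta"
    min_len: int = 300
    strict_start: bool = False
    keep_terminal_stop: bool = False
    expression_fraction: float = 0.05
    expression_set_size: int | None = None
    expression_mode: str = "fraction"
    delta_rscu_threshold: float = 0.08
    correlation_method: str = "spearman"
    pr2_universe: str = "fourfold"
    ca_input: str = "rscu"
    ordination: str = "ca"
    code_id: int = 11
    enc_curve_tolerance: float = 2.0
    round_digits: int | None = None
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def _write(df: pd.DataFrame, path: Path, round_digits: int | None, index: bool = False) -> None:
    if round_digits is not None:
        df = df.copy()
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(
                    lambda v: round_half_up(v, round_digits) if pd.notna(v) else v
                )
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage, writing all report TSVs plus a manifest.

    Returns the mapping of report name -> written path.  Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    table = standard_table(config.code_id)

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out / f"{name}.tsv"
        _write(df, path, config.round_digits, index=index)
        written[name] = path

    # --- filter ---------------------------------------------------------
    try:
        records = read_sequences(config.input_path, config.input_format)
        annotated = annotate_qc(
            records,
            table,
            min_len=config.min_len,
            strict_start=config.strict_start,
            keep_terminal_stop=config.keep_terminal_stop,
        )
        accepted = [r for r in annotated if r.accepted]
        write_filter_report(annotated, out / "filter_report.tsv")
        written["filter_report"] = out / "filter_report.tsv"
        log.info("filter: %d input, %d accepted", len(records), len(accepted))
        if not accepted:
            raise ValueError("no sequences passed the QC filter")
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
        raise PipelineError("filter", str(exc)) from exc

    # --- indices & pooled usage ----------------------------------------
    try:
        counts = {cds.gene_id: count_codons(cds, table) for cds in accepted}
        indices = [gene_indices(cds, table) for cds in accepted]
        emit("gene_indices", indices_frame(indices), index=True)
        pooled = pool_counts(list(counts.values()))
        emit("codon_usage", usage_frame(pooled, table))
        log.info("indices: %d genes, %d pooled codons", len(indices), pooled.n_codons)
    except Exception as exc:
        raise PipelineError("indices", str(exc)) from exc

    # --- optimal codons -------------------------------------------------
    try:
        hf, ties = high_frequency_codons(rscu(pooled, table), table)
        sets = select_expression_sets(
            indices,
            fraction=config.expression_fraction,
            counts_by_gene=counts,
            mode=config.expression_mode,
            set_size=config.expression_set_size,
        )
        if sets.high_counts is None or sets.low_counts is None:
            raise ValueError("expression sets are empty; no codons to compare")
        dr = delta_rscu(
            sets.high_counts, sets.low_counts, table, config.delta_rscu_threshold
        )
        call = call_optimal_codons(hf, dr, ties)
        emit("delta_rscu", dr.frame(table))
        emit(
            "optimal_codons",
            pd.DataFrame(
                {
                    "codon": list(call.optimal_codons),
                    "rscu_high": [dr.rscu_high[c] for c in call.optimal_codons],
                    "rscu_low": [dr.rscu_low[c] for c in call.optimal_codons],
                    "delta_rscu": [dr.delta[c] for c in call.optimal_codons],
                }
            ),
        )
        log.info(
            "optimal: %d high-frequency, %d high-expression, %d optimal",
            len(hf),
            len(dr.high_expression_codons),
            len(call.optimal_codons),
        )
    except Exception as exc:
        raise PipelineError("optimal", str(exc)) from exc

    # --- ordination & correlations --------------------------------------
    try:
        per_gene_rscu = [rscu(counts[cds.gene_id], table) for cds in accepted]
        if config.ca_input == "rscu":
            matrix = build_rscu_matrix(per_gene_rscu, table)
        elif config.ca_input == "counts":
            from .codon_model import informative_codons
            import numpy as np

            codons = tuple(informative_codons(table))
            vals = np.array(
                [[counts[c.gene_id].get(cd) for cd in codons] for c in accepted],
                dtype=float,
            )
            matrix = RscuMatrix(
                genes=tuple(c.gene_id for c in accepted),
                codons=codons,
                values=vals,
                imputed={},
            )
        else:
            raise ValueError(f"unknown ca_input: {config.ca_input!r}")
        coa = (
            correspondence_analysis(matrix)
            if config.ordination == "ca"
            else pca(matrix)
        )
        emit(
            "coa_axes",
            pd.DataFrame(
                {
                    "axis": [f"Axis{i + 1}" for i in range(coa.n_axes)],
                    "inertia_fraction": coa.inertia_fractions,
                    "singular_value": coa.singular_values,
                }
            ),
        )
        emit("coa_gene_coords", coa.gene_coords, index=True)
        emit("coa_codon_coords", coa.codon_coords, index=True)
        corrs = correlate_indices(indices, coa, method=config.correlation_method)
        emit("correlations", correlation_frame(corrs), index=True)
        log.info("ordination: %d axes, axis1 %.2f%%", coa.n_axes, 100 * coa.inertia_fractions[0])
    except Exception as exc:
        raise PipelineError("ordination", str(exc)) from exc

    # --- selection diagnostics ------------------------------------------
    try:
        gene_pts = [
            pr2_gene(counts[c.gene_id], universe=config.pr2_universe)
            for c in accepted
        ]
        emit(
            "pr2_gene",
            pd.DataFrame(
                {
                    "gene_id": [p.scope for p in gene_pts],
                    "g3_over_gc3": [p.x for p in gene_pts],
                    "a3_over_at3": [p.y for p in gene_pts],
                    "n_codons": [p.n_codons for p in gene_pts],
                }
            ),
        )
        count_list = [counts[c.gene_id] for c in accepted]
        for fam in fourfold_pr2_families(table):
            pts = pr2_family(count_list, fam)
            safe = fam.name.replace("(", "_").replace(")", "").replace("N", "N")
            emit(
                f"pr2_family_{safe}",
                pd.DataFrame(
                    {
                        "scope": [p.scope for p in pts],
                        "g3_over_gc3": [p.x for p in pts],
                        "a3_over_at3": [p.y for p in pts],
                        "n_codons": [p.n_codons for p in pts],
                    }
                ),
            )
        mean_y, mean_x = pr2_weighted_mean(count_list)
        encpts = enc_plot(indices)
        emit(
            "enc_plot",
            pd.DataFrame(
                {
                    "gene_id": [p.gene_id for p in encpts],
                    "gc3s": [p.gc3s for p in encpts],
                    "enc_observed": [p.enc_observed for p in encpts],
                    "enc_expected": [p.enc_expected for p in encpts],
                    "deviation": [p.deviation for p in encpts],
                }
            ),
        )
        fit = neutrality_fit(indices)
        ndf = fit.frame()
        ndf["slope"] = fit.slope
        ndf["intercept"] = fit.intercept
        ndf["pearson_r"] = fit.r
        emit("neutrality", ndf)
        summary = enc_plot_summary(encpts, config.enc_curve_tolerance)
        log.info(
            "selection: PR2 weighted mean (y=%.3f, x=%.3f); ENC plot %s; "
            "neutrality slope %.3f r %.3f",
            mean_y,
            mean_x,
            summary,
            fit.slope,
            fit.r,
        )
    except Exception as exc:
        raise PipelineError("selection", str(exc)) from exc

    # --- manifest --------------------------------------------------------
    digest = hashlib.sha256(Path(config.input_path).read_bytes()).hexdigest()
    manifest = {
        "package": "codonbias",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "input_sha256": digest,
        "n_input_records": len(records),
        "n_accepted": len(accepted),
        "pr2_weighted_mean": {"a3_over_at3": mean_y, "g3_over_gc3": mean_x},
        "enc_plot_summary": summary,
        "outputs": sorted(p.name for p in written.values()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written["manifest"] = out / "manifest.json"
    return written
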
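"""End-to-end orchestration: densities -> normalization -> calibration ->
fold changes -> termination-ratio anchoring -> absolute rates ->
factor classification.

The stage functions here are thin compositions of the module-level
operations; the command-line interface wraps them one-to-one.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping, Sequence

import pandas as pd

from . import inference, normalize, occupancy, regions
from .config import RunConfig, dump_config
from .errors import InvalidParameterError
from .regions import GeneModel, PauseWindow
from .tracks import SignalTrack

logger = logging.getLogger(__name__)

__all__ = ["compute_all_densities", "expressed_genes", "run_end_to_end", "write_tsv"]

#: Units for every column that can appear in an output table.
COLUMN_UNITS = {
    "gene_id": "id", "chrom": "chrom", "strand": "+/-",
    "pause_start": "bp (0-based)", "pause_end": "bp (0-based, exclusive)",
    "pause_sum": "counts (normalized)", "body_start": "bp (0-based)",
    "body_end": "bp (0-based, exclusive)", "body_mean": "counts/bp (normalized)",
    "condition": "label", "replicate": "label",
    "p_occ": "RNAP/pause-region", "b_occ": "RNAP/bp",
    "clipped_occupancy": "bool",
    "p_control": "density", "b_control": "density/bp",
    "p_treatment": "density", "b_treatment": "density/bp",
    "fc_p": "ratio", "fc_b": "ratio", "fc_krel": "ratio",
    "fc_kinit_lower": "ratio", "fc_kinit_upper": "ratio",
    "fc_kinit_assigned": "ratio", "clamped": "bool",
    "kpre_over_krel": "dimensionless", "boundary": "sentinel", "negative": "bool",
    "krel_control": "1/min", "krel_treatment": "1/min", "kpre": "1/min",
    "kinit_control": "RNAP/min", "kinit_treatment": "RNAP/min",
    "effective_release_control": "RNAP/min", "effective_release_treatment": "RNAP/min",
    "spacing_control": "bp/RNAP", "spacing_treatment": "bp/RNAP",
    "half_life_control": "s", "half_life_treatment": "s",
    "flags": "set", "method": "label", "A": "log10-signal", "B": "1/rank",
    "C": "log10-signal", "log_base": "base", "saturation_log": "log10-signal",
    "max_occupancy_signal": "counts/RNAP", "n_genes": "count",
    "value": "value", "cumulative_fraction": "fraction",
    "direction": "label", "dominant_mechanism": "label",
    "fraction_krel_coherent": "fraction",
    "fraction_kinit_bounds_above_1": "fraction",
    "fraction_kinit_bounds_below_1": "fraction",
    "fraction_kinit_bounds_straddle_1": "fraction",
    "fraction_kinit_coherent": "fraction",
    "n_finite": "count", "n_zero_boundary": "count",
    "n_undefined_boundary": "count", "n_negative": "count",
    "n_degenerate": "count", "n_clamped": "count",
    "median": "dimensionless", "decile_10": "dimensionless",
    "decile_90": "dimensionless", "fraction_ratio_gt_1": "fraction",
}


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a TSV with a leading comment line naming units per column."""
    units = "\t".join(COLUMN_UNITS.get(c, "unknown") for c in df.columns)
    with open(path, "w") as fh:
        fh.write(f"# units:\t{units}\n")
        df.to_csv(fh, sep="\t", index=False)


def compute_all_densities(
    tracks: Mapping[tuple[str, str], Mapping[str, SignalTrack]],
    genes: Sequence[GeneModel],
    config: RunConfig,
    control: str = "control",
) -> pd.DataFrame:
    """Raw per-sample density table for all (condition, replicate) tracks.

    By default the pause window of each gene is located once on pooled
    control-replicate signal (or the first control replicate when pooling
    in-memory arrays is not possible, e.g. bigWig input) and reused for every
    sample, so that condition comparisons are made over identical intervals.
    With ``config.recompute_pause_window`` each sample finds its own window.
    """
    windows: dict[str, PauseWindow] | None = None
    if not config.recompute_pause_window:
        control_sets = [t for (cond, _), t in tracks.items() if cond == control]
        if not control_sets:
            raise InvalidParameterError(f"no samples for control condition {control!r}")
        try:
            pooled = regions.pooled_tracks(control_sets)
        except InvalidParameterError:
            logger.info("control tracks not poolable in memory; using first replicate")
            pooled = dict(control_sets[0])
        _, windows = regions.compute_densities(
            pooled, genes, condition=control, replicate="pooled",
            search_len=config.search_len, window=config.window,
            treatment_minutes=config.treatment_minutes, cap_rate=config.k_elong,
            body_offset=config.body_offset,
        )
    frames = []
    for (cond, rep), strand_tracks in sorted(tracks.items()):
        df, _ = regions.compute_densities(
            dict(strand_tracks), genes, condition=cond, replicate=rep,
            search_len=config.search_len, window=config.window,
            treatment_minutes=config.treatment_minutes, cap_rate=config.k_elong,
            body_offset=config.body_offset, pause_windows=windows,
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def expressed_genes(raw_densities: pd.DataFrame, min_pause_sum: float) -> set[str]:
    """Gene ids passing the expression filter.

    A gene is expressed when its raw pause counts summed over all samples
    reach ``min_pause_sum`` and it has body signal in at least one sample;
    fold changes for unexpressed genes are dominated by sampling zeros.
    """
    by_gene = raw_densities.groupby("gene_id").agg(
        total_pause=("pause_sum", "sum"), max_body=("body_mean", "max")
    )
    keep = by_gene[(by_gene["total_pause"] >= min_pause_sum) & (by_gene["max_body"] > 0)]
    return set(keep.index)


def run_end_to_end(
    config: RunConfig,
    tracks: Mapping[tuple[str, str], Mapping[str, SignalTrack]],
    genes: Sequence[GeneModel],
    de_lists: Mapping[str, tuple[str, Sequence[str]]] | None = None,
    control: str = "control",
    treatment: str = "treatment",
    out_dir: str | os.PathLike | None = None,
) -> dict:
    """Run the whole workflow and (optionally) persist every stage's table.

    ``tracks`` maps (condition, replicate) to strand->SignalTrack;
    ``de_lists`` maps a label to (direction, gene ids) where direction is
    "activated" or "repressed".  Returns a dict with the raw and normalized
    densities, the occupancy calibration, the fold-change table, the
    per-gene rate report, the termination-ratio table/summary (when a
    repressed list is supplied) and one classification per DE list.
    """
    raw = compute_all_densities(tracks, genes, config, control=control)

    expressed = expressed_genes(raw, config.min_pause_sum)
    raw_expr = raw[raw["gene_id"].isin(expressed)].reset_index(drop=True)
    logger.info("%d/%d genes pass the expression filter", len(expressed),
                raw["gene_id"].nunique())

    # library-size factors from total gene counts (pause + body reads),
    # restricted to long controlGenes for globally repressive treatments
    counts = raw_expr.assign(
        total=lambda d: d["pause_sum"]
        + d["body_mean"] * (d["body_end"] - d["body_start"]),
        sample=lambda d: d["condition"] + ":" + d["replicate"],
    ).pivot_table(index="gene_id", columns="sample", values="total")
    control_ids = None
    if config.control_min_length is not None:
        lengths = raw_expr.groupby("gene_id").apply(
            lambda d: abs(int(d["body_end"].iloc[0]) - int(d["pause_start"].iloc[0])),
            include_groups=False,
        )
        control_ids = lengths[lengths > config.control_min_length].index.tolist()
    factors = normalize.size_factors(counts.fillna(0), control_genes=control_ids)

    normalized = normalize.apply_normalization(raw_expr, factors)

    ctl_sums = normalized.loc[normalized["condition"] == control, "pause_sum"]
    calibration = occupancy.max_occupancy(
        ctl_sums, has_umis=config.has_umis, percentile=config.occupancy_percentile
    )
    scaled = occupancy.scale_to_occupancy(normalized, calibration)

    fc = inference.fold_changes(scaled, control, treatment, value_cols=("p_occ", "b_occ"))

    results: dict = {
        "raw_densities": raw,
        "densities": scaled,
        "size_factors": factors,
        "calibration": calibration,
        "fold_changes": fc,
        "classifications": {},
    }

    de_lists = de_lists or {}
    for label, (direction, ids) in de_lists.items():
        if direction == "repressed" and "trp_ratio" not in results:
            sub = fc[fc["gene_id"].isin(set(ids))]
            if not sub.empty:
                table, summary = inference.infer_termination_ratio_genomewide(
                    sub, target_fc_kinit=config.target_fc_kinit,
                    offset=config.clamp_offset,
                )
                results["trp_ratio"] = table
                results["trp_summary"] = summary

    rates = inference.absolute_rate_report(
        scaled, control, treatment, calibration=calibration,
        k_elong=config.k_elong, r=config.r,
    )
    results["rates"] = rates

    for label, (direction, ids) in de_lists.items():
        try:
            results["classifications"][label] = inference.classify_factor_mechanism(
                rates, ids, direction
            )
        except InvalidParameterError as exc:
            logger.warning("classification for %s skipped: %s", label, exc)

    if out_dir is not None:
        out = os.fspath(out_dir)
        os.makedirs(out, exist_ok=True)
        dump_config(config, os.path.join(out, "resolved_config.toml"))
        write_tsv(raw, os.path.join(out, "raw_densities.tsv"))
        write_tsv(scaled, os.path.join(out, "densities.tsv"))
        write_tsv(calibration.to_frame(), os.path.join(out, "calibration.tsv"))
        write_tsv(fc, os.path.join(out, "fold_changes.tsv"))
        write_tsv(rates, os.path.join(out, "rates.tsv"))
        if "trp_ratio" in results:
            write_tsv(results["trp_ratio"], os.path.join(out, "trp_ratio.tsv"))
            write_tsv(
                pd.DataFrame([results["trp_summary"]]),
                os.path.join(out, "trp_summary.tsv"),
            )
        for label, summary in results["classifications"].items():
            flat = {k: v for k, v in summary.items() if not isinstance(v, pd.DataFrame)}
            write_tsv(pd.DataFrame([flat]), os.path.join(out, f"classify_{label}.tsv"))
            for key in ("ecdf_fc_krel", "ecdf_fc_kinit_lower", "ecdf_fc_kinit_upper"):
                write_tsv(summary[key], os.path.join(out, f"{label}_{key}.tsv"))
    return results
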
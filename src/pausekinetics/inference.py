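"""Dataset-level inference: fold changes, the triptolide-anchored
termination/release ratio, absolute rates, half-lives and factor
classification.

Fold changes in pause (``fc_p``) and body (``fc_b``) density bound the fold
change in initiation between them; the pause-release fold change is
``fc_b / fc_p`` regardless of normalization.  An initiation inhibitor of
known genome-wide efficacy (triptolide: fold change ~0.25) anchors the
per-gene initiation fold change, from which each gene's
``k_pre / k_rel(control)`` follows.  With an assumed elongation rate and a
termination-to-release ratio ``r``, every gene gets absolute rates, an
effective release rate, a body polymerase spacing and a paused-polymerase
half-life per condition.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .errors import ClampError, InvalidParameterError
from .kinetics import Boundary
from .occupancy import SaturationFit

logger = logging.getLogger(__name__)

__all__ = [
    "clamp_initiation_fold_change",
    "fold_changes",
    "infer_termination_ratio_genomewide",
    "absolute_rate_report",
    "classify_factor_mechanism",
    "ecdf_table",
]


def clamp_initiation_fold_change(
    bounds: tuple[float, float],
    target: float,
    offset: float = 0.05,
) -> tuple[float, bool]:
    """Assign an initiation fold change given its per-gene bounds.

    If ``target`` lies within [lower, upper] it is used as-is.  Otherwise
    the bound closest to the target is moved into the interior by the
    fractional ``offset`` — (1-offset) x upper when clamping from above,
    (1+offset) x lower from below — so the assigned value never sits exactly
    on a bound (which would make the termination/release ratio zero or
    undefined).

    Returns (assigned, clamped).
    """
    lower, upper = bounds
    if not (0 < lower <= upper):
        raise InvalidParameterError(f"need 0 < lower <= upper, got {bounds!r}")
    if not (0 < offset < 1):
        raise InvalidParameterError(f"offset must be in (0, 1), got {offset!r}")
    if not target > 0:
        raise InvalidParameterError(f"target must be > 0, got {target!r}")
    if lower <= target <= upper:
        return target, False
    if target > upper:
        assigned = (1.0 - offset) * upper
        if assigned <= lower:
            raise ClampError(
                f"offset {offset} pushes assigned value {assigned:g} across "
                f"the lower bound {lower:g}"
            )
    else:
        assigned = (1.0 + offset) * lower
        if assigned >= upper:
            raise ClampError(
                f"offset {offset} pushes assigned value {assigned:g} across "
                f"the upper bound {upper:g}"
            )
    return assigned, True


def fold_changes(
    densities: pd.DataFrame,
    control: str,
    treatment: str,
    value_cols: tuple[str, str] = ("pause_sum", "body_mean"),
) -> pd.DataFrame:
    """Per-gene fold changes between two conditions of a density table.

    Expects one row per gene per condition (replicates already averaged).
    Genes with a zero pause or body density in either condition are excluded
    (ratios undefined; no pseudocounts) and logged.

    Returns columns gene_id, p_control, b_control, p_treatment, b_treatment,
    fc_p, fc_b, fc_krel, fc_kinit_lower, fc_kinit_upper.
    """
    pcol, bcol = value_cols
    ctl = densities[densities["condition"] == control].set_index("gene_id")
    trt = densities[densities["condition"] == treatment].set_index("gene_id")
    shared = ctl.index.intersection(trt.index)
    rows = []
    n_dropped = 0
    for gid in shared:
        pc, bc = float(ctl.at[gid, pcol]), float(ctl.at[gid, bcol])
        pt, bt = float(trt.at[gid, pcol]), float(trt.at[gid, bcol])
        if min(pc, bc, pt, bt) <= 0:
            n_dropped += 1
            continue
        fc_p, fc_b = pt / pc, bt / bc
        lo, up = kinetics.fold_change_initiation_bounds(fc_p, fc_b)
        rows.append({
            "gene_id": gid,
            "p_control": pc, "b_control": bc,
            "p_treatment": pt, "b_treatment": bt,
            "fc_p": fc_p, "fc_b": fc_b,
            "fc_krel": kinetics.fold_change_pause_release(fc_b, fc_p),
            "fc_kinit_lower": lo, "fc_kinit_upper": up,
        })
    if n_dropped:
        logger.info("%d genes with zero density in a condition excluded", n_dropped)
    return pd.DataFrame(rows)


def infer_termination_ratio_genomewide(
    records: pd.DataFrame,
    target_fc_kinit: float = 0.25,
    offset: float = 0.05,
    tol: float = kinetics.BOUNDARY_TOL,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene k_pre/k_rel(control) anchored to a known initiation fold change.

    ``records`` needs fc_p, fc_b, fc_krel and the initiation bounds (from
    :func:`fold_changes`), restricted to the repressed-gene set for an
    initiation inhibitor.  Each gene's initiation fold change is clamped to
    its bounds and the termination/release relation applied.

    Returns the per-gene table (columns fc_kinit_assigned, clamped,
    kpre_over_krel, boundary, negative) and a summary dict with the median,
    interdecile range and the fraction of genes with ratio > 1, plus counts
    of sentinel/negative/degenerate genes.
    """
    if records.empty:
        raise InvalidParameterError("empty gene set")
    out = records.copy()
    assigned, clamped, ratios, boundaries, negatives = [], [], [], [], []
    n_degenerate = 0
    for row in out.itertuples(index=False):
        try:
            a, c = clamp_initiation_fold_change(
                (row.fc_kinit_lower, row.fc_kinit_upper), target_fc_kinit, offset
            )
        except ClampError:
            n_degenerate += 1
            assigned.append(np.nan); clamped.append(True)
            ratios.append(np.nan); boundaries.append("degenerate"); negatives.append(False)
            continue
        res = kinetics.termination_release_ratio(row.fc_krel, a, row.fc_p, tol=tol)
        assigned.append(a)
        clamped.append(c)
        ratios.append(res.value if res.value is not None else np.nan)
        boundaries.append(res.boundary.value if res.boundary else "")
        negatives.append(res.negative)
    out["fc_kinit_assigned"] = assigned
    out["clamped"] = clamped
    out["kpre_over_krel"] = ratios
    out["boundary"] = boundaries
    out["negative"] = negatives

    finite = out.loc[
        out["kpre_over_krel"].notna() & ~out["negative"], "kpre_over_krel"
    ]
    summary = {
        "n_genes": int(len(out)),
        "n_finite": int(len(finite)),
        "n_zero_boundary": int((out["boundary"] == Boundary.ZERO_BOUNDARY.value).sum()),
        "n_undefined_boundary": int(
            (out["boundary"] == Boundary.UNDEFINED_BOUNDARY.value).sum()
        ),
        "n_negative": int(out["negative"].sum()),
        "n_degenerate": n_degenerate,
        "n_clamped": int(out["clamped"].sum()),
        "median": float(np.median(finite)) if len(finite) else np.nan,
        "decile_10": float(np.percentile(finite, 10)) if len(finite) else np.nan,
        "decile_90": float(np.percentile(finite, 90)) if len(finite) else np.nan,
        "fraction_ratio_gt_1": float((finite > 1).mean()) if len(finite) else np.nan,
    }
    return out, summary


RATE_REPORT_COLUMNS = [
    "gene_id", "fc_p", "fc_b", "fc_krel",
    "fc_kinit_lower", "fc_kinit_upper", "fc_kinit_assigned",
    "kpre_over_krel",
    "krel_control", "krel_treatment",
    "kpre",
    "kinit_control", "kinit_treatment",
    "effective_release_control", "effective_release_treatment",
    "spacing_control", "spacing_treatment",
    "half_life_control", "half_life_treatment",
    "flags",
]


def absolute_rate_report(
    scaled_densities: pd.DataFrame,
    control: str,
    treatment: str,
    calibration: SaturationFit | None = None,
    k_elong: float = 2000.0,
    r: float = 6.7,
) -> pd.DataFrame:
    """Per-gene absolute rates, spacings and half-lives in both conditions.

    ``scaled_densities`` must carry occupancy columns ``p_occ``/``b_occ``
    (see :func:`pausekinetics.occupancy.scale_to_occupancy`).  Premature
    termination is assumed constant between conditions at
    ``k_pre = r * k_rel(control)``.  One row per gene
    (:data:`RATE_REPORT_COLUMNS`); half-lives in seconds.
    """
    if k_elong <= 0:
        raise InvalidParameterError("k_elong must be > 0")
    if r < 0:
        raise InvalidParameterError("r must be >= 0")
    fc = fold_changes(
        scaled_densities, control, treatment, value_cols=("p_occ", "b_occ")
    )
    clip_flags: dict[str, bool] = {}
    if "clipped_occupancy" in scaled_densities.columns:
        clip_flags = (
            scaled_densities.groupby("gene_id")["clipped_occupancy"].any().to_dict()
        )
    rows = []
    for row in fc.itertuples(index=False):
        krel_c = kinetics.pause_release_rate(k_elong, row.p_control, row.b_control)
        krel_t = kinetics.pause_release_rate(k_elong, row.p_treatment, row.b_treatment)
        kpre = r * krel_c
        kinit_c = kinetics.initiation_rate(row.p_control, row.b_control, kpre, k_elong)
        kinit_t = kinetics.initiation_rate(row.p_treatment, row.b_treatment, kpre, k_elong)
        fc_kinit = kinetics.fold_change_initiation_given_ratio(row.fc_p, row.fc_krel, r)
        flags = set()
        if clip_flags.get(row.gene_id, False):
            flags.add("clipped_occupancy")
        rows.append({
            "gene_id": row.gene_id,
            "fc_p": row.fc_p, "fc_b": row.fc_b, "fc_krel": row.fc_krel,
            "fc_kinit_lower": row.fc_kinit_lower,
            "fc_kinit_upper": row.fc_kinit_upper,
            "fc_kinit_assigned": fc_kinit,
            "kpre_over_krel": r,
            "krel_control": krel_c, "krel_treatment": krel_t,
            "kpre": kpre,
            "kinit_control": kinit_c, "kinit_treatment": kinit_t,
            "effective_release_control":
                kinetics.effective_pause_release(krel_c, row.p_control),
            "effective_release_treatment":
                kinetics.effective_pause_release(krel_t, row.p_treatment),
            "spacing_control": kinetics.polymerase_spacing(row.b_control),
            "spacing_treatment": kinetics.polymerase_spacing(row.b_treatment),
            "half_life_control": kinetics.pause_half_life(kpre, krel_c),
            "half_life_treatment": kinetics.pause_half_life(kpre, krel_t),
            "flags": ",".join(sorted(flags)),
        })
    return pd.DataFrame(rows, columns=RATE_REPORT_COLUMNS)


def ecdf_table(values: Sequence[float]) -> pd.DataFrame:
    """Empirical CDF as a two-column table (value, cumulative_fraction)."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({
        "value": v,
        "cumulative_fraction": np.arange(1, v.size + 1) / v.size if v.size else [],
    })


def classify_factor_mechanism(
    reports: pd.DataFrame,
    gene_set: Sequence[str],
    direction: str,
) -> dict:
    """Summarize whether a perturbed factor regulates initiation or pause release.

    ``reports`` is a per-gene table with fc_krel and the initiation-bound
    columns; ``gene_set`` the differentially expressed genes for the factor;
    ``direction`` "activated" (fold changes expected > 1) or "repressed"
    (< 1).  Reports, with no hidden thresholds, the fraction of genes whose
    pause-release change is in the expected direction and the fractions
    whose initiation bounds lie entirely below 1, entirely above 1, or
    straddle 1, plus ECDF tables for plotting.  The dominant coherent change
    names the factor an initiation or pause-release regulator.
    """
    if direction not in ("activated", "repressed"):
        raise InvalidParameterError("direction must be 'activated' or 'repressed'")
    if len(gene_set) == 0:
        raise InvalidParameterError("gene_set must be nonempty")
    sub = reports[reports["gene_id"].isin(set(gene_set))]
    n = len(sub)
    if n == 0:
        raise InvalidParameterError("no genes from gene_set present in reports")

    def frac(mask: pd.Series) -> float:
        return float(mask.mean())

    coherent_krel = (
        sub["fc_krel"] > 1 if direction == "activated" else sub["fc_krel"] < 1
    )
    bounds_above = (sub["fc_kinit_lower"] > 1) & (sub["fc_kinit_upper"] > 1)
    bounds_below = (sub["fc_kinit_lower"] < 1) & (sub["fc_kinit_upper"] < 1)
    coherent_kinit = bounds_above if direction == "activated" else bounds_below
    frac_krel = frac(coherent_krel)
    frac_kinit = frac(coherent_kinit)
    return {
        "n_genes": n,
        "direction": direction,
        "fraction_krel_coherent": frac_krel,
        "fraction_kinit_bounds_above_1": frac(bounds_above),
        "fraction_kinit_bounds_below_1": frac(bounds_below),
        "fraction_kinit_bounds_straddle_1": frac(~bounds_above & ~bounds_below),
        "fraction_kinit_coherent": frac_kinit,
        "dominant_mechanism":
            "pause_release" if frac_krel > frac_kinit
            else "initiation" if frac_kinit > frac_krel
            else "mixed",
        "ecdf_fc_krel": ecdf_table(sub["fc_krel"]),
        "ecdf_fc_kinit_lower": ecdf_table(sub["fc_kinit_lower"]),
        "ecdf_fc_kinit_upper": ecdf_table(sub["fc_kinit_upper"]),
    }
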
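# Methods

## The compartment model

A gene is reduced to two compartments: the promoter-proximal pause region
(density *p*, polymerases per pause region once occupancy-scaled) and the
gene body (density *b*, polymerases per bp). The model is the linear system

    dp/dt = k_init − (k_pre + k_rel)·p
    db/dt = k_rel·p − k_elong·b

Assumptions:

* **Steady state.** Pause turnover (seconds to a minute) is much faster than
  the treatment times of kinetic experiments (tens of minutes), so the
  measured densities are treated as steady states.
* **Constant k_pre and k_elong between conditions.** Only initiation and
  pause release are considered regulated; premature termination and
  elongation are held fixed for a gene across the comparison.
* **Averaged elongation.** Within-gene elongation-rate variation is averaged
  away because *b* is a mean over the body; a single representative
  `k_elong` (default 2000 bp/min) is used for all genes. All absolute rates
  scale linearly with this choice, while every ratio of rates and every
  fold change between conditions is invariant to it.
* **No bursting.** Genes are assumed continuously active; allele-level
  on/off dynamics would rescale the occupancy calibration and are out of
  scope.

Trajectories of the system are computed in closed form via the matrix
exponential of the affine-augmented system (exact for any step size,
including the degenerate case `k_elong = k_pre + k_rel`); numerical stepping
is used only as an independent cross-check in the tests.

## From tracks to densities

The pause window is the 50 bp interval of maximal summed signal within 200 bp
(PRO-seq) or 300 bp (GRO-seq) downstream of the TSS; window sums are computed
per-window (not as cumulative-sum differences) so that results, including tie
breaks toward the TSS, agree exactly with exhaustive enumeration. Minus-strand
genes are processed on flipped coordinates so a single code path sees
"downstream" as increasing offsets. The gene body runs from 500 bp past the
pause window to the TTS, truncated to the distance a polymerase can travel
during the treatment (`treatment_minutes × k_elong`, e.g. 25 kb at 12.5 min).
The cap is anchored at the body start rather than the TSS; the two anchorings
differ by at most the search length plus offset (≤ 700 bp at default
settings) and the body-start anchoring matches the interpretation that the
cap bounds how far treatment-era polymerases clear.

By default each gene's pause window is located once on pooled control
replicates and reused for the treatment samples, so both conditions are
summed over identical intervals; `recompute_pause_window` switches to
per-sample windows for users who expect pause-site repositioning.

Library sizes are equalized by median-of-ratios size factors computed from
total gene counts (pause + body). For globally repressive treatments,
`control_min_length` restricts the estimator to long genes whose distal
bodies are unaffected within the treatment time. Replicates are averaged
after normalization. Genes are retained when their raw pause counts summed
over all samples reach `min_pause_sum` (default 10) and they have body
signal; genes with a zero pause or body density in either condition are
excluded from fold changes rather than pseudocounted, since the model's
ratios are undefined at zero.

## Occupancy calibration

Assuming a fully occupied pause region holds one polymerase and that some
genes approach full occupancy, ranked log10 pause sums are fitted with
`y = A·tanh(B·x) + C`; the plateau `10^(A+C)` is the signal of one
polymerase. The fit is initialized at half the log-range amplitude, the mean
log-sum, and a bend at mid-rank, with A and B bounded positive — tanh fits
are initialization-sensitive. Base 10 is recorded in the calibration record.
The plateau estimate is accepted only for duplicate-free (UMI) libraries and
only when it lands between the median pause sum and 1000× the maximum;
otherwise (and always for non-UMI libraries) the pause sum at a configurable
percentile of ranked sums (default 90th) is used. The stability of
incremental fits truncated at the 70th–100th percentiles serves as a
diagnostic: a few-fold variation indicates a usable saturation, orders of
magnitude indicate duplicate inflation. Pause sums above saturation (multicopy
genes, mapping artifacts) are clipped to occupancy 1 and flagged rather than
dropped. One calibration per dataset, computed from the control condition,
is shared across conditions so absolute rates are comparable.

## Inference

Per gene, fc(k_rel) = fc(b)/fc(p) and fc(k_init) ∈ [min, max](fc(p), fc(b)).
For an initiation inhibitor of known genome-wide efficacy the initiation
fold change is anchored to a target (default 0.25): genes whose bounds span
the target use it directly; otherwise the bound closest to the target is
moved *into the interior* by a 5% offset. Interior placement (rather than a
fixed-sign offset) guarantees the assigned value stays within its admissible
bounds and never sits exactly on one, where the termination/release relation

    k_pre/k_rel = (fc(k_rel) − X)/(X − 1),   X = fc(k_init)/fc(p)

degenerates to zero or an undefined value. Boundary cases are detected at a
relative tolerance of 1e-9 — tight enough not to mask genuinely
near-boundary genes — and reported as sentinels; finite negative ratios
(possible only when a user-supplied initiation fold change lies outside its
bounds) are flagged, excluded from summaries and counted, never clipped.
Genes with collapsed bounds (fc(p) = fc(b), i.e. fc(k_rel) = 1) cannot be
clamped interior and are counted as degenerate. Summaries report the median,
the 10th–90th percentile range (linear interpolation) and the fraction of
genes with ratio > 1.

Absolute rates assume a termination-to-release ratio `r` (default 6.7, the
genome-wide median from triptolide anchoring) for datasets without their own
initiation-inhibitor arm: `k_rel = k_elong·b/p` per condition,
`k_pre = r·k_rel(control)` held constant, `k_init = p·k_pre + k_elong·b`
(occupancy-scaled densities required; the unscaled variant is rejected
because an absolute rate on arbitrary units is meaningless), effective
release `k_rel·p`, spacing `1/b`, and half-life `60·ln2/(k_pre + k_rel)`
seconds.

Factor classification reports, with no hidden thresholds, the fraction of DE
genes whose pause-release change is coherent with the perturbation direction
and the fractions whose initiation bounds lie entirely below/above/straddle
1, plus ECDF tables; the dominant coherent change names the mechanism.

## Synthetic data

The generator draws per-gene rates from log-normals with medians anchored to
genome-scale estimates — k_rel median 0.86/min, k_init median 0.5 RNAP/min,
log-sigma 0.8 (spanning roughly the observed interdecile ranges), k_pre =
r·k_rel with r = 6.7, k_elong = 2000 bp/min — computes steady states, and
concentrates the expected pause mass in a spike or a 5 bp-sigma Gaussian
footprint inside the search region, with uniform expected body signal.
Counts are Poisson per base; per-sample library multipliers exercise
normalization. Genes sit on one synthetic chromosome, non-overlapping,
1 kb apart, alternating strands. Seeds are mandatory.

Emulated features of real data: concentrated pause signal with an arbitrary
peak position, body signal proportional to k_rel·p/k_elong, shot noise,
library-size differences, strandedness. Not emulated: mappability and
multicopy artifacts (the saturation uptick is constructed directly in the
calibration tests instead), overdispersion beyond Poisson (config option,
off by default — the model treats densities as steady-state means), bursting,
within-gene elongation variation, and TSS mis-annotation. Passing recovery
tests on these fixtures therefore validates the inference algebra and the
extraction pipeline, not robustness to alignment artifacts.

Simulation sizes in the test suite (250–2000 genes, 2×10⁵–10⁶ reads, two
replicates) are chosen as the smallest at which Poisson error on the
summaries is well below the assertion tolerances.

## Numerical choices and degenerate inputs

* Closed-form propagation for trajectories; no integration tolerances.
* Exact window sums for tie-break fidelity (see above).
* `k_pre + k_rel = 0` → degenerate-steady-state error; zero pause density →
  undefined-rate error; zero body density → zero release, infinite spacing
  sentinel.
* Percentiles computed with numpy's linear interpolation.
* TSVs are written deterministically; reruns are byte-identical.

## Known limitations

* Absolute rates inherit the uncertainty of the assumed elongation rate
  (linearly) and of the occupancy calibration (k_init inversely; k_pre/k_rel
  not at all).
* The anchored termination/release ratio is unidentifiable for genes whose
  pause-release change is exactly 1 and noisy near that boundary.
* A single genome-wide anchor for initiation-inhibitor efficacy ignores
  gene-to-gene variation in inhibitor sensitivity.
* DE gene lists are trusted inputs; no differential-expression calling is
  performed.
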
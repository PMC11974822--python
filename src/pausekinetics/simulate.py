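"""Synthetic nascent-transcription datasets with known kinetic ground truth.

Each simulated gene gets a rate set drawn from log-normal distributions
anchored to genome-wide medians (pause release ~0.86/min, initiation
~0.5 RNAP/min, termination r x release, elongation 2 kb/min).  Steady-state
pause and body densities follow the compartment model; expected per-base
counts are the densities times a common occupancy signal, concentrated in a
narrow pause footprint (spike or Gaussian) and uniform over the body; reads
are Poisson.  Two conditions are related by user-chosen per-gene fold
changes on initiation and/or pause release, with per-sample library-size
multipliers to exercise normalization.

What this emulates — and what it does not — is discussed in the package
methods note; notably there is no mappability artifact, no bursting and no
within-gene elongation-rate variation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kinetics import RateSet, steady_state
from .regions import GeneModel
from .tracks import ArrayTrack, write_bedgraph

__all__ = [
    "SimulatedGene",
    "SimulatedDataset",
    "sample_gene_rates",
    "generate_condition_pair",
    "write_fixture_tracks",
]

CHROM = "chrSim"
INTERGENIC_GAP = 1000  # bp between simulated genes; avoids window ambiguity


@dataclass(frozen=True)
class SimulatedGene:
    """Layout and ground-truth rates for one simulated gene.

    Offsets are sense-strand distances from the TSS.  ``pause_mass_end`` is
    the first base past the pause footprint; the gene body runs from
    ``pause_mass_end + 500`` for ``body_len`` bases.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    rates: RateSet
    pause_peak: int
    pause_shape: str  # "spike" | "gaussian"
    body_len: int

    @property
    def pause_mass_end(self) -> int:
        return self.pause_peak + 1 if self.pause_shape == "spike" else self.pause_peak + 13

    @property
    def body_start_offset(self) -> int:
        return self.pause_mass_end + 500

    def as_gene_model(self) -> GeneModel:
        return GeneModel(
            gene_id=self.gene_id, chrom=self.chrom, strand=self.strand,
            tss=self.tss, tts=self.tts,
        )


def sample_gene_rates(
    n_genes: int,
    seed: int,
    krel_median: float = 0.86,
    krel_sigma: float = 0.8,
    kinit_median: float = 0.5,
    kinit_sigma: float = 0.8,
    r: float = 6.7,
    k_elong: float = 2000.0,
    body_len_range: tuple[int, int] = (2000, 8000),
    search_len: int = 200,
    window: int = 50,
) -> list[SimulatedGene]:
    """Draw reproducible per-gene rate sets and lay genes on one chromosome.

    k_rel and k_init are log-normal with the given medians (log-scale sigma);
    k_pre = r * k_rel; k_elong is shared.  Pause peaks sit uniformly within
    the search region (with margin so a width-``window`` pause window can
    contain the footprint); strands alternate; genes are spaced 1 kb apart.
    """
    if n_genes < 1:
        raise InvalidParameterError("n_genes must be >= 1")
    if krel_sigma < 0 or kinit_sigma < 0 or krel_median <= 0 or kinit_median <= 0:
        raise InvalidParameterError("rate distribution parameters invalid")
    if r < 0 or k_elong <= 0:
        raise InvalidParameterError("r must be >= 0 and k_elong > 0")
    rng = np.random.default_rng(seed)
    krel = np.exp(rng.normal(np.log(krel_median), krel_sigma, n_genes))
    kinit = np.exp(rng.normal(np.log(kinit_median), kinit_sigma, n_genes))
    body_lens = rng.integers(body_len_range[0], body_len_range[1] + 1, n_genes)
    # footprint must fit a single pause window: keep the peak away from edges
    peaks = rng.integers(window - 1, search_len - 13, n_genes)
    shapes = rng.choice(["spike", "gaussian"], n_genes)
    genes: list[SimulatedGene] = []
    cursor = INTERGENIC_GAP
    for i in range(n_genes):
        shape = str(shapes[i])
        mass_end = int(peaks[i]) + (1 if shape == "spike" else 13)
        length = mass_end + 500 + int(body_lens[i])
        genes.append(
            SimulatedGene(
                gene_id=f"gene{i:05d}",
                chrom=CHROM,
                strand="+" if i % 2 == 0 else "-",
                tss=cursor,
                tts=cursor + length,
                rates=RateSet(
                    k_init=float(kinit[i]),
                    k_pre=r * float(krel[i]),
                    k_rel=float(krel[i]),
                    k_elong=k_elong,
                ),
                pause_peak=int(peaks[i]),
                pause_shape=shape,
                body_len=int(body_lens[i]),
            )
        )
        cursor += length + INTERGENIC_GAP
    return genes


@dataclass
class SimulatedDataset:
    """Tracks, annotation and ground truth for a two-condition experiment."""

    genes: list[SimulatedGene]
    tracks: dict[tuple[str, str], dict[str, ArrayTrack]]  # (condition, rep) -> strand
    truth: pd.DataFrame
    occupancy_signal: float
    library_multipliers: dict[tuple[str, str], float]

    def gene_models(self) -> list[GeneModel]:
        return [g.as_gene_model() for g in self.genes]


def _gene_mean_profile(gene: SimulatedGene, rates: RateSet, occ: float) -> np.ndarray:
    """Expected per-base counts along the sense strand of one gene."""
    ss = steady_state(rates)
    profile = np.zeros(gene.tts - gene.tss)
    pause_total = ss.p * occ
    if gene.pause_shape == "spike":
        profile[gene.pause_peak] = pause_total
    else:
        offsets = np.arange(-12, 13)
        weights = np.exp(-0.5 * (offsets / 5.0) ** 2)
        weights /= weights.sum()
        profile[gene.pause_peak + offsets] = pause_total * weights
    body = slice(gene.body_start_offset, gene.body_start_offset + gene.body_len)
    profile[body] = ss.b * occ
    return profile


def generate_condition_pair(
    genes: Sequence[SimulatedGene],
    perturbation: Mapping[str, tuple[float, float]],
    depth: float,
    seed: int,
    n_replicates: int = 2,
    library_multipliers: Mapping[tuple[str, str], float] | None = None,
    conditions: tuple[str, str] = ("control", "treatment"),
) -> SimulatedDataset:
    """Poisson count tracks for control and treatment plus a truth table.

    ``perturbation`` maps gene_id -> (fold change in k_init, fold change in
    k_rel); genes not listed are unperturbed.  ``depth`` sets the expected
    total read count of one control replicate at library multiplier 1; the
    occupancy signal (counts per polymerase) is derived from it so that
    expected counts are proportional to the steady-state densities.
    ``library_multipliers`` maps (condition, replicate) -> scale, default 1.
    """
    if depth <= 0:
        raise InvalidParameterError("depth must be > 0")
    rng = np.random.default_rng(seed)
    control, treatment = conditions

    total_units = 0.0
    per_gene = []
    for gene in genes:
        fc_kinit, fc_krel = perturbation.get(gene.gene_id, (1.0, 1.0))
        rc = gene.rates
        rt = RateSet(
            k_init=rc.k_init * fc_kinit,
            k_pre=rc.k_pre,
            k_rel=rc.k_rel * fc_krel,
            k_elong=rc.k_elong,
        )
        ss_c, ss_t = steady_state(rc), steady_state(rt)
        total_units += ss_c.p + ss_c.b * gene.body_len
        per_gene.append((gene, rc, rt, ss_c, ss_t, fc_kinit, fc_krel))
    occ = depth / total_units

    chrom_len = max(g.tts for g in genes) + INTERGENIC_GAP
    mean_tracks: dict[str, dict[str, np.ndarray]] = {}
    for cond in conditions:
        means = {"+": np.zeros(chrom_len), "-": np.zeros(chrom_len)}
        for gene, rc, rt, *_ in per_gene:
            rates = rc if cond == control else rt
            profile = _gene_mean_profile(gene, rates, occ)
            if gene.strand == "+":
                means["+"][gene.tss : gene.tts] += profile
            else:
                means["-"][gene.tss : gene.tts] += profile[::-1]
        mean_tracks[cond] = means

    reps = [f"rep{i + 1}" for i in range(n_replicates)]
    multipliers = dict(library_multipliers or {})
    tracks: dict[tuple[str, str], dict[str, ArrayTrack]] = {}
    for cond in conditions:
        for rep in reps:
            mult = float(multipliers.setdefault((cond, rep), 1.0))
            if mult <= 0:
                raise InvalidParameterError("library multipliers must be > 0")
            sampled = {
                strand: rng.poisson(mult * mean).astype(float)
                for strand, mean in mean_tracks[cond].items()
            }
            tracks[(cond, rep)] = {s: ArrayTrack({CHROM: a}) for s, a in sampled.items()}

    truth = pd.DataFrame(
        [
            {
                "gene_id": gene.gene_id,
                "chrom": gene.chrom,
                "strand": gene.strand,
                "tss": gene.tss,
                "tts": gene.tts,
                "pause_peak": gene.pause_peak,
                "pause_shape": gene.pause_shape,
                "body_len": gene.body_len,
                "k_init": rc.k_init, "k_pre": rc.k_pre,
                "k_rel": rc.k_rel, "k_elong": rc.k_elong,
                "fc_kinit": fc_kinit, "fc_krel": fc_krel,
                "p_control": ss_c.p, "b_control": ss_c.b,
                "p_treatment": ss_t.p, "b_treatment": ss_t.b,
                "fc_p": ss_t.p / ss_c.p, "fc_b": ss_t.b / ss_c.b,
            }
            for gene, rc, rt, ss_c, ss_t, fc_kinit, fc_krel in per_gene
        ]
    )
    return SimulatedDataset(
        genes=list(genes),
        tracks=tracks,
        truth=truth,
        occupancy_signal=occ,
        library_multipliers={k: float(v) for k, v in multipliers.items()},
    )


def write_fixture_tracks(dataset: SimulatedDataset, out_dir: str | os.PathLike) -> dict:
    """Write bedGraphs, BED6 annotation, DE lists, truth table and a manifest.

    Minus-strand bedGraphs carry negative values (run-on convention); the
    track readers return magnitudes, so a write/read round trip is exact.
    Returns the manifest dict (also written as manifest.json).
    """
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"tracks": {}, "occupancy_signal": dataset.occupancy_signal}
    for (cond, rep), strand_tracks in dataset.tracks.items():
        for strand, track in strand_tracks.items():
            tag = "plus" if strand == "+" else "minus"
            path = os.path.join(out, f"{cond}_{rep}_{tag}.bedGraph")
            write_bedgraph(track.arrays, path, negate=(strand == "-"))
            manifest["tracks"][f"{cond}:{rep}:{strand}"] = path

    bed_path = os.path.join(out, "genes.bed")
    with open(bed_path, "w") as fh:
        for g in dataset.genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tts}\t{g.gene_id}\t0\t{g.strand}\n")
    manifest["annotation"] = bed_path

    truth_path = os.path.join(out, "truth.tsv")
    dataset.truth.to_csv(truth_path, sep="\t", index=False)
    manifest["truth"] = truth_path

    # DE lists from the generating fold change in expected body density
    repressed = dataset.truth.loc[dataset.truth["fc_b"] < 1, "gene_id"]
    activated = dataset.truth.loc[dataset.truth["fc_b"] > 1, "gene_id"]
    for name, ids in (("repressed", repressed), ("activated", activated)):
        path = os.path.join(out, f"{name}_genes.txt")
        with open(path, "w") as fh:
            fh.write("\n".join(ids) + ("\n" if len(ids) else ""))
        manifest[f"{name}_genes"] = path

    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
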
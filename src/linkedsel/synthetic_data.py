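"""Synthetic genomes and polymorphism with known linked-selection ground truth.

The generator emulates the inputs the inference consumes — annotation
intervals laid out as gene models (UTR / exon / long-intron blocks separated
by intergenic stretches), a piecewise-constant genetic map, lineage-specific
substitutions placed inside their annotation class, a neutral divergence
table for the mutation-rate proxy, and per-site polymorphism — under the
package's own generative law: pairwise differences at a neutral site occur
with probability pi(x) = pi0 u_rel / (pi0 u_rel + 1/B(x) + S_scaled(x)),
with B and S_scaled computed from the true parameters.

Two observation modes are provided. ``independent_pairs`` draws
n_diff ~ Binomial(C(n,2), pi(x)) per site — exactly the model implied by the
composite likelihood, so parameter recovery is exact up to Monte-Carlo
error. ``allele_counts`` draws a site frequency from a neutral-SFS-shaped
law (polymorphic with probability pi(x) * H_{n-1}, derived count j with
probability proportional to 1/j) whose expected heterozygosity is also
pi(x), but whose pair indicators are correlated within a site — for
realism/robustness checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from linkedsel.genome_data import (
    AnnotationSet,
    GeneticMap,
    GenomicInterval,
    MutationProxySummary,
    NeutralSiteTable,
    SubstitutionSet,
    mask_by_recombination,
    mutation_proxy,
)
from linkedsel.inference import ModelParams, predicted_pi
from linkedsel.selection_effects import (
    EffectiveSizeContext,
    SelectionGrid,
    build_bs_lookup,
    build_sweep_lookup,
    bs_factor,
    sweep_rate_scaled,
)

logger = logging.getLogger(__name__)

BS_CLASSES = ("coding", "utr", "intron", "intergenic")
CS_CLASSES = ("nonsyn", "utr", "intron")
#: substitution class -> annotation class containing its positions
SUB_PARENT = {"nonsyn": "coding", "utr": "utr", "intron": "intron"}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults describe a 4 x 25 Mb autosomal genome with ~20% coding, ~5% UTR
    and ~15% long-intron sequence, recombination cycling through
    0.5 / 1.5 / 2.5 / 3.5 cM/Mb segments, a 20-allele sample, pi0 = 0.02,
    lineage depth k_bar = 0.1 substitutions per neutral site, and a sparse
    truth: one purifying mass (u_d = 5e-9 at t = 10^-3.5 on coding) and two
    sweep masses on amino-acid substitutions (4% at s = 10^-3.5, 35% at
    s = 10^-5.5).
    """

    seed: int
    n_chroms: int = 4
    chrom_length_bp: int = 25_000_000
    # gene geometry (means of gamma-distributed block lengths, bp)
    exon_mean: float = 500.0
    n_exons: int = 3
    utr_mean: float = 190.0
    intron_mean: float = 565.0
    intergenic_mean: float = 4340.0
    length_shape: float = 8.0
    gap_shape: float = 4.0
    min_block: int = 30
    min_intron: int = 81          # "long" introns only
    # heterogeneous gene architectures, regionally clustered (as in real
    # genomes, where compact intronless genes, long-intron genes and
    # UTR-rich genes cluster): type -> (prob, n_exons, exon/utr/intron
    # length multipliers); probabilities must sum to 1
    gene_types: dict = field(default_factory=lambda: {
        "compact":     (0.30, 2, 1.5, 0.7, 0.0),
        "long_intron": (0.25, 4, 0.75, 0.7, 2.0),
        "utr_rich":    (0.15, 2, 1.5, 4.0, 0.5),
        "baseline":    (0.30, 3, 1.0, 1.0, 1.0),
    })
    region_bp: int = 250_000       # scale of gene-type clustering
    region_dominance: float = 0.65  # prob. of a region's dominant type
    # recombination
    rec_levels: tuple = (0.5, 1.5, 2.5, 3.5)   # cM/Mb
    rec_segment_bp: int = 2_500_000
    # substitutions per bp of the parent annotation
    sub_density: dict = field(default_factory=lambda: {
        "nonsyn": 2e-3, "utr": 1e-3, "intron": 5e-4})
    # neutral (synonymous-like) site density per coding bp
    neutral_site_density: float = 0.02
    # divergence informative-site density per coding bp: ~all synonymous
    # sites (divergence needs no sequencing panel, unlike the thinned
    # polymorphism panel), so the sliding proxy window spans a short range
    divergence_site_density: float = 0.25
    # population / mutation parameters
    n_alleles: int = 20
    pi0: float = 0.02
    k_bar: float = 0.1
    mu_site: float = 5e-9          # direct per-site mutation rate -> Ne
    # relative mutation-rate landscape (cycled segments; (1.0,) = constant)
    u_rel_levels: tuple = (1.0,)
    u_rel_segment_bp: int = 5_000_000
    proxy_window: int = 6000
    # true selection parameters: class -> {selection coefficient: weight}
    true_bs: dict = field(default_factory=lambda: {
        "coding": {10 ** -3.5: 5e-9}})
    true_cs: dict = field(default_factory=lambda: {
        "nonsyn": {10 ** -3.5: 0.04, 10 ** -5.5: 0.35}})

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        gene_span = (self.n_exons * self.exon_mean + 2 * self.utr_mean
                     + (self.n_exons - 1) * self.intron_mean)
        if gene_span + self.intergenic_mean > self.chrom_length_bp:
            raise ValueError("gene unit longer than chromosome: infeasible geometry")
        for d in self.sub_density.values():
            if d < 0:
                raise ValueError("substitution densities must be >= 0")

    @property
    def Ne(self) -> float:
        return self.pi0 / (4.0 * self.mu_site)

    def grid(self) -> SelectionGrid:
        return SelectionGrid.default()

    def true_params(self) -> ModelParams:
        grid = self.grid()
        w_bs = np.zeros((grid.n_t, len(BS_CLASSES)))
        for cls_, masses in self.true_bs.items():
            i = BS_CLASSES.index(cls_)
            for t, w in masses.items():
                g = int(np.argmin(np.abs(np.log(grid.t_values) - np.log(t))))
                w_bs[g, i] += w
        w_cs = np.zeros((grid.n_s, len(CS_CLASSES)))
        for cls_, masses in self.true_cs.items():
            j = CS_CLASSES.index(cls_)
            for s, w in masses.items():
                k = int(np.argmin(np.abs(np.log(grid.s_values) - np.log(s))))
                w_cs[k, j] += w
        return ModelParams(pi0=self.pi0, w_bs=w_bs, w_cs=w_cs,
                           bs_classes=list(BS_CLASSES),
                           cs_classes=list(CS_CLASSES))


@dataclass
class SyntheticGenome:
    """A generated genome: the four inference inputs plus bookkeeping."""

    annotations: AnnotationSet
    gmap: GeneticMap
    substitutions: SubstitutionSet
    divergence: pd.DataFrame
    neutral_positions: dict[str, np.ndarray]
    u_rel_true: dict[str, np.ndarray]      # aligned with neutral_positions
    config: SyntheticConfig


@dataclass
class GroundTruth:
    """True parameters and per-site tracks used to generate the data.

    The tracks are computed from the true parameters with the package's own
    lookup machinery, so they are consistent with ``params`` by construction.
    """

    params: ModelParams
    B: np.ndarray
    S_scaled: np.ndarray
    pi: np.ndarray
    Ne: float
    k_bar: float


def _draw_len(rng, mean: float, shape: float, minimum: int) -> int:
    return max(int(round(rng.gamma(shape, mean / shape))), minimum)


def make_genome(config: SyntheticConfig) -> SyntheticGenome:
    """Generate annotations, genetic map, substitutions and divergence.

    Deterministic given ``config.seed``; substitutions fall only inside
    their class's intervals; divergence informative sites coincide with the
    neutral (synonymous-like) site panel.
    """
    rng = np.random.default_rng(config.seed)
    records: list[GenomicInterval] = []
    sub_records: list[tuple[str, int, str]] = []
    neutral_positions: dict[str, np.ndarray] = {}
    u_rel_true: dict[str, np.ndarray] = {}
    map_segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    div_frames = []

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        L = config.chrom_length_bp
        # --- gene geometry ---------------------------------------------------
        blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in BS_CLASSES}
        type_names = list(config.gene_types)
        type_probs = np.array([config.gene_types[t][0] for t in type_names])
        type_probs = type_probs / type_probs.sum()
        region_dominant: dict[int, str] = {}
        cursor = 0
        while True:
            gap = _draw_len(rng, config.intergenic_mean, config.gap_shape, 1)
            # regionally clustered gene architecture
            region = int(cursor // config.region_bp)
            if region not in region_dominant:
                region_dominant[region] = rng.choice(type_names, p=type_probs)
            if rng.random() < config.region_dominance:
                gtype = region_dominant[region]
            else:
                gtype = rng.choice(type_names, p=type_probs)
            _, n_ex, exon_mul, utr_mul, intron_mul = config.gene_types[gtype]
            gene: list[tuple[str, int]] = [("utr", _draw_len(
                rng, config.utr_mean * utr_mul, config.length_shape,
                config.min_block))]
            for e in range(n_ex):
                gene.append(("coding", _draw_len(
                    rng, config.exon_mean * exon_mul, config.length_shape,
                    config.min_block)))
                if e < n_ex - 1 and intron_mul > 0:
                    gene.append(("intron", _draw_len(
                        rng, config.intron_mean * intron_mul,
                        config.length_shape, config.min_intron)))
            gene.append(("utr", _draw_len(
                rng, config.utr_mean * utr_mul, config.length_shape,
                config.min_block)))
            gene_len = sum(l for _, l in gene)
            if cursor + gap + gene_len >= L:
                if cursor < L:
                    blocks["intergenic"].append((cursor, L))
                break
            blocks["intergenic"].append((cursor, cursor + gap))
            p = cursor + gap
            for cls_, l in gene:
                blocks[cls_].append((p, p + l))
                p += l
            cursor = p
        for cls_, lst in blocks.items():
            records.extend(GenomicInterval(chrom, s, e, cls_) for s, e in lst)

        # --- recombination map ----------------------------------------------
        starts = np.arange(0, L, config.rec_segment_bp, dtype=np.int64)
        ends = np.minimum(starts + config.rec_segment_bp, L)
        rates = np.array([config.rec_levels[i % len(config.rec_levels)]
                          for i in range(len(starts))], dtype=np.float64)
        map_segments[chrom] = (starts.astype(float), ends.astype(float), rates)

        # --- substitutions ---------------------------------------------------
        sub_pos_by_parent: dict[str, np.ndarray] = {}
        for sub_cls, parent in SUB_PARENT.items():
            dens = config.sub_density.get(sub_cls, 0.0)
            if dens <= 0 or not blocks[parent]:
                sub_pos_by_parent[sub_cls] = np.array([], dtype=np.int64)
                continue
            bp = np.concatenate([np.arange(s, e, dtype=np.int64)
                                 for s, e in blocks[parent]])
            pos = bp[rng.random(len(bp)) < dens]
            sub_pos_by_parent[sub_cls] = pos
            sub_records.extend((chrom, int(p), sub_cls) for p in pos)

        # --- neutral site panel (synonymous-like, inside coding) -------------
        coding_bp = np.concatenate([np.arange(s, e, dtype=np.int64)
                                    for s, e in blocks["coding"]]) \
            if blocks["coding"] else np.array([], dtype=np.int64)
        taken = set(sub_pos_by_parent["nonsyn"].tolist())
        cand = coding_bp[rng.random(len(coding_bp)) < config.neutral_site_density]
        cand = cand[~np.isin(cand, list(taken))] if taken else cand
        neutral_positions[chrom] = cand

        # --- true mutation-rate landscape ------------------------------------
        levels = np.asarray(config.u_rel_levels, dtype=np.float64)
        seg_idx = (cand // config.u_rel_segment_bp) % len(levels)
        u_rel_true[chrom] = levels[seg_idx] / levels.mean()

        # --- divergence panel (denser, independent thinning of coding) -------
        div_pos = coding_bp[rng.random(len(coding_bp))
                            < config.divergence_site_density]
        if taken:
            div_pos = div_pos[~np.isin(div_pos, list(taken))]
        div_seg = (div_pos // config.u_rel_segment_bp) % len(levels)
        div_u_true = levels[div_seg] / levels.mean()
        is_sub = (rng.random(len(div_pos))
                  < config.k_bar * div_u_true).astype(np.int64)
        div_frames.append(pd.DataFrame(
            {"chrom": chrom, "pos": div_pos, "is_substitution": is_sub}))

    annotations = AnnotationSet.from_records(records, classes=list(BS_CLASSES))
    gmap = GeneticMap.from_rates(map_segments)
    substitutions = SubstitutionSet.from_records(sub_records,
                                                 classes=list(CS_CLASSES))
    divergence = pd.concat(div_frames, ignore_index=True)
    return SyntheticGenome(annotations=annotations, gmap=gmap,
                           substitutions=substitutions, divergence=divergence,
                           neutral_positions=neutral_positions,
                           u_rel_true=u_rel_true, config=config)


def true_tracks(genome: SyntheticGenome, table: NeutralSiteTable,
                params: ModelParams | None = None, *, method: str = "auto"
                ) -> GroundTruth:
    """Compute the true B, S_scaled and pi tracks for a site table."""
    cfg = genome.config
    params = params or cfg.true_params()
    grid = cfg.grid()
    ctx = EffectiveSizeContext(Ne=cfg.Ne)
    bs_lk = build_bs_lookup(table, genome.annotations, grid, genome.gmap,
                            method=method)
    sw_lk = build_sweep_lookup(table, genome.substitutions, grid, genome.gmap,
                               ctx, method=method)
    B = bs_factor(params.w_bs, bs_lk)
    S = sweep_rate_scaled(params.w_cs, sw_lk, params.pi0, cfg.k_bar)
    levels = np.asarray(cfg.u_rel_levels, dtype=np.float64)
    seg_idx = (table.pos // cfg.u_rel_segment_bp) % len(levels)
    u_true = levels[seg_idx] / levels.mean()
    pi = predicted_pi(params.pi0, B, S, u_true)
    return GroundTruth(params=params, B=B, S_scaled=S, pi=pi, Ne=cfg.Ne,
                       k_bar=cfg.k_bar)


def simulate_polymorphism(genome: SyntheticGenome,
                          truth: ModelParams | None = None,
                          n_alleles: int | None = None,
                          mode: str = "independent_pairs",
                          seed: int | None = None, *,
                          method: str = "auto",
                          ) -> tuple[NeutralSiteTable, GroundTruth,
                                     MutationProxySummary]:
    """Draw per-site polymorphism under the generative law.

    Returns the neutral site table (u_rel attached from the divergence
    table's sliding-window proxy, recombination masks applied), the ground
    truth tracks, and the mutation-proxy summary. The aggregate mean
    heterozygosity is Monte-Carlo checked against the model expectation at
    generation time.
    """
    cfg = genome.config
    if mode not in ("independent_pairs", "allele_counts"):
        raise ValueError(f"unknown mode {mode!r}")
    n = n_alleles if n_alleles is not None else cfg.n_alleles
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    chroms = sorted(genome.neutral_positions)
    chrom_arr = np.concatenate([np.full(len(genome.neutral_positions[c]), c,
                                        dtype=object) for c in chroms])
    pos_arr = np.concatenate([genome.neutral_positions[c] for c in chroms])

    # estimated mutation-rate proxy from the divergence table
    div_proxy, proxy = mutation_proxy(genome.divergence,
                                      window_size=cfg.proxy_window)
    div_proxy = div_proxy.sort_values(["chrom", "pos"], kind="stable")
    u_est = np.empty(len(pos_arr))
    off = 0
    for c in chroms:
        npos = genome.neutral_positions[c]
        sub = div_proxy[div_proxy["chrom"] == c]
        u_est[off:off + len(npos)] = np.interp(
            npos.astype(float), sub["pos"].to_numpy(dtype=float),
            sub["u_rel"].to_numpy())
        off += len(npos)

    skeleton = NeutralSiteTable.from_arrays(
        chrom_arr, pos_arr,
        np.zeros(len(pos_arr), dtype=np.int64),
        np.full(len(pos_arr), n * (n - 1) // 2, dtype=np.int64),
        u_rel=u_est)
    truth_gt = true_tracks(genome, skeleton, truth, method=method)
    pi = truth_gt.pi
    if np.any(pi <= 0) or np.any(pi >= 1):
        raise ValueError("generative pi(x) outside (0, 1); aborting generation")

    n_pairs = n * (n - 1) // 2
    if mode == "independent_pairs":
        n_diff = rng.binomial(n_pairs, pi)
    else:
        H = np.sum(1.0 / np.arange(1, n))
        p_poly = pi * H
        if np.any(p_poly >= 1):
            raise ValueError("pi * H_{n-1} >= 1: sample too small for the "
                             "SFS-shaped observation mode")
        poly = rng.random(len(pi)) < p_poly
        j_support = np.arange(1, n)
        j_probs = (1.0 / j_support) / H
        j = rng.choice(j_support, size=int(poly.sum()), p=j_probs)
        n_diff = np.zeros(len(pi), dtype=np.int64)
        n_diff[poly] = j * (n - j)
    n_same = n_pairs - n_diff

    table = NeutralSiteTable.from_arrays(chrom_arr, pos_arr, n_diff, n_same,
                                         u_rel=u_est)
    table = mask_by_recombination(table, genome.gmap)
    table.meta["mode"] = mode
    table.meta["n_alleles"] = n

    # Monte-Carlo sanity check: realized mean het vs model expectation
    mean_het = float(n_diff.sum()) / (n_pairs * len(pi))
    mean_pi = float(pi.mean())
    se = np.sqrt(float((pi * (1 - pi)).sum()) / n_pairs) / len(pi)
    infl = 3.0 if mode == "allele_counts" else 1.0
    if abs(mean_het - mean_pi) > 6.0 * se * infl:
        logger.warning("generated mean heterozygosity %.3g deviates from "
                       "expectation %.3g beyond Monte-Carlo bounds",
                       mean_het, mean_pi)
    return table, truth_gt, proxy
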
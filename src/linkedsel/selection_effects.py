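"""Background-selection and sweep coalescence-rate lookup tables.

The composite-likelihood model discretises the distribution of fitness
effects on a grid of selection coefficients. For every neutral site x the
package precomputes, per grid point and annotation class,

* ``b(x | t_g, i_B)`` -- the background-selection exponent per unit
  deleterious mutation rate: the sum over selected positions y (same
  chromosome) of ``t / (t + r(x, y) (1 - t))**2``;
* ``s(x | s_k, i_S)`` -- the sweep kernel: the sum over substitutions y of
  class i_S of ``exp(-r(x, y) * tau(s_k, Ne))``, with tau the diffusion
  approximation to the fixation time.

Both tables are linear in the grid weights, so the likelihood of any weight
configuration is evaluated from the tables without revisiting the genome.

Two computation paths are provided: an exact per-position sum (quadratic
cost; the reference at desk scale) and a distance-binned approximation using
geometric bins in Morgans with exact per-bin selected-site counts (near
linear cost; used for chromosome-scale data). ``method="auto"`` selects by
problem size.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from linkedsel.genome_data import AnnotationSet, GeneticMap, NeutralSiteTable, SubstitutionSet

EULER_GAMMA = 0.5772156649015329

#: site-chunk length for vectorised lookup construction
_CHUNK = 4096
#: auto path selection: exact when sites x selected-positions stays below this
_AUTO_EXACT_LIMIT = 2.0e8


@dataclass(frozen=True)
class SelectionGrid:
    """Grid of deleterious (t) and beneficial (s) selection coefficients."""

    t_values: np.ndarray
    s_values: np.ndarray

    def __post_init__(self):
        for name, v in (("t_values", self.t_values), ("s_values", self.s_values)):
            v = np.asarray(v, dtype=np.float64)
            if np.any(v <= 0) or np.any(v >= 1):
                raise ValueError(f"{name} must lie in (0, 1)")
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, v)

    @classmethod
    def default(cls) -> "SelectionGrid":
        """Five log-linear point masses, 10^-5.5 .. 10^-1.5, for both t and s."""
        v = 10.0 ** np.arange(-5.5, -1.0, 1.0)
        return cls(t_values=v, s_values=v.copy())

    @property
    def n_t(self) -> int:
        return len(self.t_values)

    @property
    def n_s(self) -> int:
        return len(self.s_values)


@dataclass(frozen=True)
class EffectiveSizeContext:
    """Average effective population size used in the fixation-time formula."""

    Ne: float
    gamma: float = EULER_GAMMA

    def __post_init__(self):
        if not self.Ne > 0:
            raise ValueError("Ne must be positive")


def bs_exponent_single(t, r):
    """Per-site, per-unit-u_d background-selection exponent t / (t + r(1-t))^2.

    ``t`` is the heterozygous deleterious selection coefficient, ``r`` the
    genetic distance in Morgans. Equals 1/t at r = 0 and decreases strictly
    in r; multiplied by the deleterious mutation rate u_d it gives one
    selected position's contribution to -log B.
    """
    t = np.asarray(t, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if np.any(t <= 0) or np.any(t >= 1):
        raise ValueError("t must lie in (0, 1)")
    if np.any(r < 0):
        raise ValueError("genetic distance must be non-negative")
    out = t / (t + r * (1.0 - t)) ** 2
    return float(out) if out.ndim == 0 else out


def fixation_time(s, Ne):
    """Expected fixation time (generations) of a beneficial additive allele.

    Diffusion approximation: tau = 2 (ln(4 Ne s) + gamma - (4 Ne s)^-1) / s.
    Requires 4 Ne s > 1; a warning is issued below 10, where the
    approximation degrades.
    """
    s = np.asarray(s, dtype=np.float64)
    x = 4.0 * Ne * s
    if np.any(x <= 1.0):
        raise ValueError("fixation_time requires 4*Ne*s > 1")
    if np.any(x < 10.0):
        warnings.warn("4*Ne*s < 10: diffusion approximation for the fixation "
                      "time degrades", RuntimeWarning, stacklevel=2)
    out = 2.0 * (np.log(x) + EULER_GAMMA - 1.0 / x) / s
    return float(out) if out.ndim == 0 else out


def _bs_cutoff(t: float, eps: float) -> float:
    """Distance beyond which one position's BS exponent falls below eps."""
    if eps <= 0:
        return np.inf
    root = np.sqrt(t / eps)
    return max((root - t) / (1.0 - t), 0.0)


def _sweep_cutoff(tau: float, eps: float) -> float:
    if eps <= 0:
        return np.inf
    if eps >= 1.0:
        return 0.0
    return np.log(1.0 / eps) / tau


@dataclass
class BSLookup:
    """b[x, g, i_B]: BS exponent per unit u_d at site x, grid point g, class i_B."""

    b: np.ndarray
    classes: list[str]
    t_values: np.ndarray
    eps_trunc: float
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.b.shape[0]


@dataclass
class SweepLookup:
    """s[x, k, i_S]: summed sweep kernel at site x, grid point k, class i_S."""

    s: np.ndarray
    classes: list[str]
    s_values: np.ndarray
    tau_values: np.ndarray
    eps_trunc: float
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.s.shape[0]


# ----------------------------------------------------------------------------
# geometric distance bins (shared by the binned BS and sweep paths)
# ----------------------------------------------------------------------------

def _geometric_bins(d_max: float, d_min: float = 1e-8, ratio: float = 1.06
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges [0, d_min, d_min*ratio, ...] covering (0, d_max], plus
    representative distances (arithmetic midpoint for the first bin,
    geometric mean elsewhere)."""
    if d_max <= d_min:
        edges = np.array([0.0, d_min])
    else:
        n = int(np.ceil(np.log(d_max / d_min) / np.log(ratio))) + 1
        edges = np.concatenate([[0.0], d_min * ratio ** np.arange(n + 1)])
    reps = np.sqrt(edges[:-1] * edges[1:])
    reps[0] = edges[1] / 2.0
    return edges, reps


def _selected_runs(blocks: np.ndarray, gmap: GeneticMap, chrom: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Interp knots (xs in Morgans, ys cumulative selected bp) of the
    piecewise-linear 'selected bp so far' function for one class/chromosome.

    Each annotation block is cut at genetic-map knots so the count grows
    linearly in genetic position within each piece and is flat between
    blocks.
    """
    bp_knots, _ = gmap.knots[chrom]
    xs_list, ys_list = [], []
    cum = 0.0
    for s, e in blocks:
        inner = bp_knots[(bp_knots > s) & (bp_knots < e)]
        bounds = np.concatenate([[s], inner, [e]]).astype(np.float64)
        m = gmap.cum_morgans(chrom, bounds)
        xs_list.append(m)
        ys_list.append(cum + np.concatenate([[0.0], np.cumsum(np.diff(bounds))]))
        cum += float(e - s)
    if not xs_list:
        return np.array([]), np.array([])
    xs = np.concatenate(xs_list)
    ys = np.concatenate(ys_list)
    # guard against zero-rate segments producing duplicate genetic positions
    xs = np.maximum.accumulate(xs) + 1e-18 * np.arange(len(xs))
    return xs, ys


def _binned_counts_linear(m_sites: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                          edges: np.ndarray) -> np.ndarray:
    """Selected-bp counts per distance bin around each site (both directions),
    from the piecewise-linear cumulative function (xs, ys)."""
    if len(xs) == 0:
        return np.zeros((len(m_sites), len(edges) - 1))
    total = ys[-1]
    q_r = m_sites[:, None] + edges[None, :]
    q_l = m_sites[:, None] - edges[None, :]
    L_r = np.interp(q_r, xs, ys, left=0.0, right=total)
    L_l = np.interp(q_l, xs, ys, left=0.0, right=total)
    return (L_r[:, 1:] - L_r[:, :-1]) + (L_l[:, :-1] - L_l[:, 1:])


def _binned_counts_points(m_sites: np.ndarray, m_points: np.ndarray,
                          edges: np.ndarray) -> np.ndarray:
    """Point (substitution) counts per distance bin around each site."""
    if len(m_points) == 0:
        return np.zeros((len(m_sites), len(edges) - 1))
    q_r = m_sites[:, None] + edges[None, :]
    q_l = m_sites[:, None] - edges[None, :]
    right = np.searchsorted(m_points, q_r, side="right")
    left = np.searchsorted(m_points, q_l, side="left")
    counts = (right[:, 1:] - right[:, :-1]).astype(np.float64)
    counts += (left[:, :-1] - left[:, 1:]).astype(np.float64)
    # points exactly at the focal position fall in neither half-open side
    at_focal = (np.searchsorted(m_points, m_sites, side="right")
                - np.searchsorted(m_points, m_sites, side="left"))
    counts[:, 0] += at_focal
    return counts


# ----------------------------------------------------------------------------
# lookup construction
# ----------------------------------------------------------------------------

def _positions_per_bp(blocks: np.ndarray) -> np.ndarray:
    """Explicitly enumerate every selected bp of a block list (exact path)."""
    if len(blocks) == 0:
        return np.array([], dtype=np.int64)
    return np.concatenate([np.arange(s, e, dtype=np.int64) for s, e in blocks])


def _choose_method(method: str, n_pairs: float) -> str:
    if method != "auto":
        return method
    return "exact" if n_pairs <= _AUTO_EXACT_LIMIT else "binned"


def build_bs_lookup(table: NeutralSiteTable, annotations: AnnotationSet,
                    grid: SelectionGrid, gmap: GeneticMap, *,
                    eps_trunc: float = 1e-10, method: str = "auto",
                    bin_ratio: float = 1.03, bin_d_min: float = 1e-9) -> BSLookup:
    """Build the background-selection lookup b[x, g, i_B] for all table sites.

    ``eps_trunc`` truncates per-position contributions below that value
    (a distance cutoff per grid point; 0 disables truncation). ``method`` is
    "exact" (per-bp sums), "binned" (geometric distance bins with exact
    per-bin bp counts) or "auto".
    """
    t_vals = grid.t_values
    classes = annotations.classes
    n_sites = len(table)
    b = np.zeros((n_sites, len(t_vals), len(classes)))
    cutoffs = np.array([_bs_cutoff(t, eps_trunc) for t in t_vals])

    total_pairs = 0.0
    for chrom in table.chroms():
        n_x = len(table.chrom_slice(chrom))
        n_y = sum(int((arr[:, 1] - arr[:, 0]).sum())
                  for c in classes for arr in [annotations.intervals[c].get(chrom, np.empty((0, 2)))])
        total_pairs += float(n_x) * n_y
    used = _choose_method(method, total_pairs)

    for chrom in table.chroms():
        idx = table.chrom_slice(chrom)
        m_x = gmap.cum_morgans(chrom, table.pos[idx])
        if used == "binned":
            span_m = gmap.cum_morgans(chrom, gmap.span(chrom)[1]) - \
                gmap.cum_morgans(chrom, gmap.span(chrom)[0])
            edges, reps = _geometric_bins(max(span_m, bin_d_min * 2),
                                          d_min=bin_d_min, ratio=bin_ratio)
            kern = bs_exponent_single(t_vals[None, :], reps[:, None])
            kern = np.where(reps[:, None] <= cutoffs[None, :], kern, 0.0)
        for ci, cls_ in enumerate(classes):
            blocks = annotations.intervals[cls_].get(chrom)
            if blocks is None or len(blocks) == 0:
                continue
            if used == "exact":
                m_y = gmap.cum_morgans(chrom, _positions_per_bp(blocks))
                chunk = max(1, int(2e7 // max(len(m_y), 1)))
                for lo in range(0, len(idx), chunk):
                    sl = slice(lo, lo + chunk)
                    d = np.abs(m_x[sl, None] - m_y[None, :])
                    for gi, t in enumerate(t_vals):
                        contrib = bs_exponent_single(t, d)
                        if np.isfinite(cutoffs[gi]):
                            contrib = np.where(d <= cutoffs[gi], contrib, 0.0)
                        b[idx[sl], gi, ci] = contrib.sum(axis=1)
            else:
                xs, ys = _selected_runs(blocks, gmap, chrom)
                for lo in range(0, len(idx), _CHUNK):
                    sl = slice(lo, lo + _CHUNK)
                    counts = _binned_counts_linear(m_x[sl], xs, ys, edges)
                    b[idx[sl], :, ci] = counts @ kern
    return BSLookup(b=b, classes=list(classes), t_values=t_vals.copy(),
                    eps_trunc=eps_trunc, method=used,
                    meta={"map_checksum": map_checksum(gmap),
                          "bin_ratio": bin_ratio, "bin_d_min": bin_d_min})


def build_sweep_lookup(table: NeutralSiteTable, substitutions: SubstitutionSet,
                       grid: SelectionGrid, gmap: GeneticMap,
                       ctx: EffectiveSizeContext, *,
                       eps_trunc: float = 1e-10, method: str = "auto",
                       bin_ratio: float = 1.03, bin_d_min: float = 1e-9
                       ) -> SweepLookup:
    """Build the sweep lookup s[x, k, i_S] = sum_y exp(-r(x, y) tau(s_k, Ne))
    over same-chromosome substitutions y of class i_S.

    A substitution at the focal site's own position contributes fully
    (exp(0) = 1). Truncation and methods as for the BS lookup.
    """
    s_vals = grid.s_values
    tau_vals = np.asarray(fixation_time(s_vals, ctx.Ne))
    classes = substitutions.classes
    n_sites = len(table)
    s_tab = np.zeros((n_sites, len(s_vals), len(classes)))
    cutoffs = np.array([_sweep_cutoff(tau, eps_trunc) for tau in tau_vals])

    total_pairs = 0.0
    for chrom in table.chroms():
        n_x = len(table.chrom_slice(chrom))
        n_y = sum(len(substitutions.positions[c].get(chrom, ())) for c in classes)
        total_pairs += float(n_x) * n_y
    used = _choose_method(method, total_pairs)

    for chrom in table.chroms():
        idx = table.chrom_slice(chrom)
        m_x = gmap.cum_morgans(chrom, table.pos[idx])
        if used == "binned":
            span_m = gmap.cum_morgans(chrom, gmap.span(chrom)[1]) - \
                gmap.cum_morgans(chrom, gmap.span(chrom)[0])
            edges, reps = _geometric_bins(max(span_m, bin_d_min * 2),
                                          d_min=bin_d_min, ratio=bin_ratio)
            kern = np.exp(-reps[:, None] * tau_vals[None, :])
            kern = np.where(reps[:, None] <= cutoffs[None, :], kern, 0.0)
        for ci, cls_ in enumerate(classes):
            pos = substitutions.positions[cls_].get(chrom)
            if pos is None or len(pos) == 0:
                continue
            m_y = np.sort(gmap.cum_morgans(chrom, pos))
            if used == "exact":
                chunk = max(1, int(2e7 // max(len(m_y), 1)))
                for lo in range(0, len(idx), chunk):
                    sl = slice(lo, lo + chunk)
                    d = np.abs(m_x[sl, None] - m_y[None, :])
                    for ki, tau in enumerate(tau_vals):
                        contrib = np.exp(-d * tau)
                        if np.isfinite(cutoffs[ki]):
                            contrib = np.where(d <= cutoffs[ki], contrib, 0.0)
                        s_tab[idx[sl], ki, ci] = contrib.sum(axis=1)
            else:
                for lo in range(0, len(idx), _CHUNK):
                    sl = slice(lo, lo + _CHUNK)
                    counts = _binned_counts_points(m_x[sl], m_y, edges)
                    s_tab[idx[sl], :, ci] = counts @ kern
    return SweepLookup(s=s_tab, classes=list(classes), s_values=s_vals.copy(),
                       tau_values=tau_vals, eps_trunc=eps_trunc, method=used,
                       meta={"map_checksum": map_checksum(gmap), "Ne": ctx.Ne,
                             "bin_ratio": bin_ratio, "bin_d_min": bin_d_min})


# ----------------------------------------------------------------------------
# combining lookups with weights
# ----------------------------------------------------------------------------

def bs_factor(w_bs: np.ndarray, lookup: BSLookup, x=None) -> np.ndarray | float:
    """B(x) = exp(-sum_{i,g} w(t_g | i) b(x | t_g, i)), in (0, 1].

    ``w_bs`` has shape (G, I_B): deleterious mutation rate per site per
    generation assigned to each grid mass, per class.
    """
    w = np.asarray(w_bs, dtype=np.float64)
    if w.shape != lookup.b.shape[1:]:
        raise ValueError(f"w_bs shape {w.shape} does not match lookup "
                         f"{lookup.b.shape[1:]}")
    if np.any(w < 0):
        raise ValueError("BS weights must be non-negative")
    expo = np.einsum("xgi,gi->x", lookup.b, w)
    out = np.exp(-expo)
    if x is not None:
        return float(out[x])
    return out


def sweep_rate_scaled(w_cs: np.ndarray, lookup: SweepLookup, pi0: float,
                      k_bar: float, x=None) -> np.ndarray | float:
    """Sweep coalescence rate in units of 1/(2 Ne):
    S_scaled(x) = (2 pi0 / k_bar) * sum_{i,k} w(s_k | i) s(x | s_k, i).

    The lineage depth enters through T / 2Ne = (k_bar / 2) / pi0; weights are
    fractions of substitutions per class and must sum to at most 1 per class.
    """
    w = np.asarray(w_cs, dtype=np.float64)
    if w.shape != lookup.s.shape[1:]:
        raise ValueError(f"w_cs shape {w.shape} does not match lookup "
                         f"{lookup.s.shape[1:]}")
    if np.any(w < 0):
        raise ValueError("sweep weights must be non-negative")
    sums = w.sum(axis=0)
    if np.any(sums > 1.0 + 1e-12):
        raise ValueError("sweep weights must sum to <= 1 per class")
    if not (pi0 > 0 and k_bar > 0):
        raise ValueError("pi0 and k_bar must be positive")
    rate = (2.0 * pi0 / k_bar) * np.einsum("xki,ki->x", lookup.s, w)
    if x is not None:
        return float(rate[x])
    return rate


# ----------------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------------

def map_checksum(gmap: GeneticMap) -> str:
    h = hashlib.sha256()
    for chrom in gmap.chroms():
        bp, m = gmap.knots[chrom]
        h.update(chrom.encode())
        h.update(np.ascontiguousarray(bp).tobytes())
        h.update(np.ascontiguousarray(m).tobytes())
    return h.hexdigest()[:16]


def save_lookups(path_prefix, bs: BSLookup | None = None,
                 sweep: SweepLookup | None = None) -> None:
    """Persist lookups as <prefix>.npz with a JSON sidecar <prefix>.json."""
    arrays, side = {}, {}
    if bs is not None:
        arrays["b"] = bs.b
        arrays["t_values"] = bs.t_values
        side["bs"] = {"classes": bs.classes, "eps_trunc": bs.eps_trunc,
                      "method": bs.method, "meta": bs.meta}
    if sweep is not None:
        arrays["s"] = sweep.s
        arrays["s_values"] = sweep.s_values
        arrays["tau_values"] = sweep.tau_values
        side["sweep"] = {"classes": sweep.classes, "eps_trunc": sweep.eps_trunc,
                         "method": sweep.method, "meta": sweep.meta}
    np.savez_compressed(str(path_prefix) + ".npz", **arrays)
    with open(str(path_prefix) + ".json", "w") as fh:
        json.dump(side, fh, indent=2, default=float)


def load_lookups(path_prefix) -> tuple[BSLookup | None, SweepLookup | None]:
    with open(str(path_prefix) + ".json") as fh:
        side = json.load(fh)
    data = np.load(str(path_prefix) + ".npz")
    bs = sweep = None
    if "bs" in side:
        bs = BSLookup(b=data["b"], classes=side["bs"]["classes"],
                      t_values=data["t_values"],
                      eps_trunc=side["bs"]["eps_trunc"],
                      method=side["bs"]["method"], meta=side["bs"]["meta"])
    if "sweep" in side:
        sweep = SweepLookup(s=data["s"], classes=side["sweep"]["classes"],
                            s_values=data["s_values"],
                            tau_values=data["tau_values"],
                            eps_trunc=side["sweep"]["eps_trunc"],
                            method=side["sweep"]["method"],
                            meta=side["sweep"]["meta"])
    return bs, sweep
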
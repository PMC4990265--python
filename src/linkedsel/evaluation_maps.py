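"""Genome-wide predicted-diversity maps and evaluation statistics.

"Scaled diversity" throughout is per-site heterozygosity divided by the
local mutation-rate proxy u_rel and expressed relative to its genome-wide
(informative-pair-weighted) average; predictions are scaled the same way so
observed and predicted maps are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from linkedsel.genome_data import GeneticMap, NeutralSiteTable, SubstitutionSet
from linkedsel.inference import FitResult, ModelParams, OptConfig, fit, predicted_pi
from linkedsel.selection_effects import BSLookup, SweepLookup, bs_factor, sweep_rate_scaled


@dataclass
class DiversityMap:
    """Per-site predictions over predict-masked sites.

    ``scaled_obs`` / ``scaled_pred`` are observed / predicted scaled
    diversity (relative to their own pair-weighted genome means, stored in
    ``meta``); ``bs_rate`` = 1/B - 1 and ``cs_rate`` = S_scaled are the added
    coalescence rates of each mode in units of 1/(2 Ne).
    """

    chrom: np.ndarray
    pos: np.ndarray
    m: np.ndarray            # genetic position, Morgans
    pi: np.ndarray           # predicted heterozygosity
    B: np.ndarray
    S_scaled: np.ndarray
    scaled_pred: np.ndarray
    scaled_obs: np.ndarray
    n_pairs: np.ndarray
    u_rel: np.ndarray
    pi0: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def bs_rate(self) -> np.ndarray:
        return 1.0 / self.B - 1.0

    @property
    def cs_rate(self) -> np.ndarray:
        return self.S_scaled

    def chroms(self) -> list[str]:
        return sorted(set(self.chrom.astype(str)))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom.astype(str) == chrom)


@dataclass
class CollatedCurve:
    """Mean diversity and mode-specific coalescence rates by genetic distance
    from the substitutions of one class."""

    edges: np.ndarray        # Morgans, n_bins + 1
    mean_obs: np.ndarray
    mean_pred: np.ndarray
    mean_bs_rate: np.ndarray
    mean_cs_rate: np.ndarray
    count: np.ndarray        # (site, substitution) contributions per bin
    cls: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dist_lo": self.edges[:-1], "dist_hi": self.edges[1:],
            "mean_obs": self.mean_obs, "mean_pred": self.mean_pred,
            "mean_bs_rate": self.mean_bs_rate, "mean_cs_rate": self.mean_cs_rate,
            "count": self.count,
        })


def _weighted_mean(v: np.ndarray, w: np.ndarray) -> float:
    return float((v * w).sum() / w.sum())


def predict_map(params: ModelParams, bs_lookup: BSLookup | None,
                sweep_lookup: SweepLookup | None, table: NeutralSiteTable,
                gmap: GeneticMap, k_bar: float) -> DiversityMap:
    """Predicted diversity map over the table's predict-masked sites."""
    B = (bs_factor(params.w_bs, bs_lookup) if bs_lookup is not None
         else np.ones(len(table)))
    S = (sweep_rate_scaled(params.w_cs, sweep_lookup, params.pi0, k_bar)
         if sweep_lookup is not None else np.zeros(len(table)))
    pi = predicted_pi(params.pi0, B, S, table.u_rel)
    pm = table.predict_mask
    idx = np.flatnonzero(pm)
    m = np.empty(len(idx))
    chroms = table.chrom[idx].astype(str)
    for chrom in np.unique(chroms):
        sub = chroms == chrom
        m[sub] = gmap.cum_morgans(chrom, table.pos[idx][sub])
    w = table.n_pairs[idx].astype(np.float64)
    het = table.het[idx]
    u = table.u_rel[idx]
    obs_raw = het / u
    pred_raw = pi[idx] / u
    mean_obs = _weighted_mean(obs_raw, w)
    mean_pred = _weighted_mean(pred_raw, w)
    return DiversityMap(
        chrom=table.chrom[idx], pos=table.pos[idx], m=m, pi=pi[idx],
        B=B[idx], S_scaled=S[idx],
        scaled_pred=pred_raw / mean_pred, scaled_obs=obs_raw / mean_obs,
        n_pairs=table.n_pairs[idx], u_rel=u, pi0=params.pi0,
        meta={"mean_obs_raw": mean_obs, "mean_pred_raw": mean_pred,
              "k_bar": k_bar})


# ----------------------------------------------------------------------------
# BedGraph I/O
# ----------------------------------------------------------------------------

_TRACKS = ("scaled_pred", "scaled_obs", "B", "S_scaled")


def write_bedgraph(dmap: DiversityMap, path, track: str = "scaled_pred") -> None:
    """Write one per-site track as BedGraph (chrom, pos, pos+1, value)."""
    if track not in _TRACKS:
        raise ValueError(f"track must be one of {_TRACKS}")
    vals = getattr(dmap, track)
    with open(path, "w") as fh:
        fh.write(f"#track={track}\n")
        for c, p, v in zip(dmap.chrom.astype(str), dmap.pos, vals):
            fh.write(f"{c}\t{p}\t{p + 1}\t{float(v)!r}\n")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64,
                            "value": np.float64},
                     float_precision="round_trip")
    return df


# ----------------------------------------------------------------------------
# window R^2
# ----------------------------------------------------------------------------

def window_r2(dmap: DiversityMap, window_bp: int, min_sites: int = 100
              ) -> tuple[float, pd.DataFrame]:
    """Squared Pearson correlation between window-mean observed and predicted
    scaled diversity over non-overlapping windows of ``window_bp``.

    Window means are informative-pair-weighted; windows with fewer than
    ``min_sites`` sites are dropped. Returns (R^2, per-window table); R^2 is
    NaN when fewer than two windows remain or either vector is degenerate.
    """
    df = pd.DataFrame({
        "chrom": dmap.chrom.astype(str),
        "win": dmap.pos // window_bp,
        "obs_w": dmap.scaled_obs * dmap.n_pairs,
        "pred_w": dmap.scaled_pred * dmap.n_pairs,
        "w": dmap.n_pairs.astype(np.float64),
    })
    g = df.groupby(["chrom", "win"], sort=True)
    tab = g.agg(obs_w=("obs_w", "sum"), pred_w=("pred_w", "sum"),
                w=("w", "sum"), n_sites=("w", "size")).reset_index()
    tab["obs"] = tab["obs_w"] / tab["w"]
    tab["pred"] = tab["pred_w"] / tab["w"]
    tab["start"] = tab["win"] * window_bp
    tab = tab.drop(columns=["obs_w", "pred_w"])
    kept = tab[tab["n_sites"] >= min_sites].reset_index(drop=True)
    if len(kept) < 2 or kept["obs"].std() == 0 or kept["pred"].std() == 0:
        return float("nan"), kept
    r = np.corrcoef(kept["obs"], kept["pred"])[0, 1]
    return float(r * r), kept


# ----------------------------------------------------------------------------
# leave-one-out cross-validation over windows
# ----------------------------------------------------------------------------

@dataclass
class LoocvResult:
    windows: pd.DataFrame
    r2_in: float
    r2_out: float
    base_fit: FitResult


def loocv(table: NeutralSiteTable, bs_lookup: BSLookup | None,
          sweep_lookup: SweepLookup | None, k_bar: float, window_bp: int, *,
          variant: str = "both", opt_config: OptConfig | None = None,
          base_fit: FitResult | None = None, min_sites: int = 10,
          u_max: dict[str, float] | None = None) -> LoocvResult:
    """Out-of-sample window predictions by refitting on each window's complement.

    For every non-overlapping window of ``window_bp`` containing at least
    ``min_sites`` fit-masked sites, the model is refit using only sites
    outside the window (warm-started at the all-data optimum plus a null
    start) and the window's pair-weighted mean observed / predicted scaled
    diversity recorded. R^2 across windows is reported for both the
    out-of-sample and the in-sample (all-data fit) predictions; windows whose
    refit fails to converge are flagged and excluded from the aggregate.
    """
    cfg = opt_config or OptConfig()
    if base_fit is None:
        base_fit = fit(table, bs_lookup, sweep_lookup, k_bar, variant=variant,
                       opt_config=cfg, u_max=u_max)
    fmask = table.fit_mask
    chroms = table.chrom.astype(str)
    win_key = pd.Series(list(zip(chroms, table.pos // window_bp)))
    windows = sorted(set(win_key[fmask]))
    if len(windows) < 3:
        raise ValueError("LOOCV needs at least 3 windows with fit data")

    def _pi_for(params: ModelParams) -> np.ndarray:
        B = (bs_factor(params.w_bs, bs_lookup) if bs_lookup is not None else 1.0)
        S = (sweep_rate_scaled(params.w_cs, sweep_lookup, params.pi0, k_bar)
             if sweep_lookup is not None else 0.0)
        return predicted_pi(params.pi0,
                            np.broadcast_to(np.asarray(B, float), (len(table),)),
                            np.broadcast_to(np.asarray(S, float), (len(table),)),
                            table.u_rel)

    pi_in = _pi_for(base_fit.params)
    w_all = table.n_pairs.astype(np.float64)
    het = table.het
    u = table.u_rel
    refit_cfg = _dc_replace(cfg, n_starts=1)
    rows = []
    for key in windows:
        in_win = (win_key == key).to_numpy() & fmask
        n_sites = int(in_win.sum())
        if n_sites < min_sites:
            continue
        res = fit(table, bs_lookup, sweep_lookup, k_bar, variant=variant,
                  opt_config=refit_cfg, site_mask=fmask & ~in_win,
                  extra_starts=[base_fit.params], u_max=u_max)
        pi_out = _pi_for(res.params)
        w = w_all[in_win]
        rows.append({
            "chrom": key[0], "start": int(key[1]) * window_bp,
            "n_sites": n_sites,
            "obs": _weighted_mean(het[in_win] / u[in_win], w),
            "pred_in": _weighted_mean(pi_in[in_win] / u[in_win], w),
            "pred_out": _weighted_mean(pi_out[in_win] / u[in_win], w),
            "converged": bool(res.converged),
        })
    tab = pd.DataFrame(rows)
    ok = tab["converged"].to_numpy()
    use = tab[ok]

    def _r2(a, b):
        if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)

    return LoocvResult(windows=tab,
                       r2_in=_r2(use["obs"], use["pred_in"]),
                       r2_out=_r2(use["obs"], use["pred_out"]),
                       base_fit=base_fit)


# ----------------------------------------------------------------------------
# collated diversity around substitutions
# ----------------------------------------------------------------------------

def collate(dmap: DiversityMap, substitutions: SubstitutionSet, cls: str,
            gmap: GeneticMap, max_dist_morgans: float, n_bins: int = 50
            ) -> CollatedCurve:
    """Collate diversity and mode rates by genetic distance from class-``cls``
    substitutions.

    Every (site, substitution) pair within ``max_dist_morgans`` on the same
    chromosome contributes once to its linear distance bin; bin means are
    informative-pair-weighted.
    """
    if substitutions.count(cls) == 0:
        raise ValueError(f"no substitutions of class {cls!r}")
    edges = np.linspace(0.0, max_dist_morgans, n_bins + 1)
    sums = {k: np.zeros(n_bins) for k in ("obs", "pred", "bs", "cs", "w")}
    count = np.zeros(n_bins, dtype=np.int64)
    for chrom in dmap.chroms():
        idx = dmap.chrom_slice(chrom)
        if len(idx) == 0:
            continue
        m_sites = dmap.m[idx]
        order = np.argsort(m_sites, kind="stable")
        ms = m_sites[order]
        site_idx = idx[order]
        subs_pos = substitutions.positions[cls].get(chrom)
        if subs_pos is None or len(subs_pos) == 0:
            continue
        m_subs = gmap.cum_morgans(chrom, subs_pos)
        w = dmap.n_pairs[site_idx].astype(np.float64)
        obs = dmap.scaled_obs[site_idx]
        pred = dmap.scaled_pred[site_idx]
        bsr = dmap.bs_rate[site_idx]
        csr = dmap.cs_rate[site_idx]
        for m0 in m_subs:
            lo = np.searchsorted(ms, m0 - max_dist_morgans, side="left")
            hi = np.searchsorted(ms, m0 + max_dist_morgans, side="right")
            if hi <= lo:
                continue
            d = np.abs(ms[lo:hi] - m0)
            b = np.minimum((d / max_dist_morgans * n_bins).astype(np.int64),
                           n_bins - 1)
            ww = w[lo:hi]
            np.add.at(sums["w"], b, ww)
            np.add.at(sums["obs"], b, obs[lo:hi] * ww)
            np.add.at(sums["pred"], b, pred[lo:hi] * ww)
            np.add.at(sums["bs"], b, bsr[lo:hi] * ww)
            np.add.at(sums["cs"], b, csr[lo:hi] * ww)
            np.add.at(count, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = {k: np.where(sums["w"] > 0, sums[k] / sums["w"], np.nan)
                for k in ("obs", "pred", "bs", "cs")}
    return CollatedCurve(edges=edges, mean_obs=mean["obs"],
                         mean_pred=mean["pred"], mean_bs_rate=mean["bs"],
                         mean_cs_rate=mean["cs"], count=count, cls=cls)


# ----------------------------------------------------------------------------
# stratification into equal-data bins
# ----------------------------------------------------------------------------

@dataclass
class StratifyResult:
    bins: pd.DataFrame
    spearman_rho: float
    pibar_over_pi0: float
    reduction: float          # 1 - pibar_over_pi0

    def percentile_ratio(self, frac_lo: float, frac_hi: float) -> float:
        """Mean observed/neutral diversity ratio over a band of predicted-
        diversity percentiles (e.g. the top 1%: frac_lo=0.99, frac_hi=1)."""
        b = self.bins
        cum = b["w"].cumsum() / b["w"].sum()
        sel = (cum > frac_lo) & (cum <= frac_hi + 1e-12)
        if not sel.any():
            sel = cum >= frac_lo
        return float((b.loc[sel, "ratio"] * b.loc[sel, "w"]).sum()
                     / b.loc[sel, "w"].sum())


def stratify(dmap: DiversityMap, n_bins: int) -> StratifyResult:
    """Sort sites by predicted scaled diversity into ``n_bins`` equal-data
    bins (equal cumulative informative-pair counts, greedy partition; ties in
    the prediction broken by genomic order).

    Reports per-bin pair-weighted mean observed/predicted scaled diversity,
    the Spearman correlation between the bin means, and the mean reduction:
    the ratio of observed diversity to the level predicted without linked
    selection (pi_null = pi0 u_rel / (pi0 u_rel + 1), per site).
    """
    n = len(dmap)
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds number of sites {n}")
    order = np.argsort(dmap.scaled_pred, kind="stable")
    w = dmap.n_pairs[order].astype(np.float64)
    cw = np.cumsum(w)
    targets = cw[-1] * np.arange(1, n_bins) / n_bins
    bounds = np.concatenate([[0], np.searchsorted(cw, targets) + 1, [n]])
    bounds = np.maximum.accumulate(bounds)
    obs = dmap.scaled_obs[order]
    pred = dmap.scaled_pred[order]
    het_over_u = (dmap.scaled_obs * dmap.meta.get("mean_obs_raw", 1.0))[order]
    u = dmap.u_rel[order]
    pi_null_over_u = dmap.pi0 / (dmap.pi0 * u + 1.0)
    rows = []
    for j in range(n_bins):
        sl = slice(bounds[j], bounds[j + 1])
        if sl.stop <= sl.start:
            raise ValueError("empty stratification bin; reduce n_bins")
        ww = w[sl]
        rows.append({
            "bin": j, "n_sites": sl.stop - sl.start, "w": float(ww.sum()),
            "obs": _weighted_mean(obs[sl], ww),
            "pred": _weighted_mean(pred[sl], ww),
            "ratio": (_weighted_mean(het_over_u[sl], ww)
                      / _weighted_mean(pi_null_over_u[sl], ww)),
        })
    bins = pd.DataFrame(rows)
    rho = float(stats.spearmanr(bins["obs"], bins["pred"]).statistic)
    ratio_all = (_weighted_mean(het_over_u, w) / _weighted_mean(pi_null_over_u, w))
    return StratifyResult(bins=bins, spearman_rho=rho,
                          pibar_over_pi0=ratio_all, reduction=1.0 - ratio_all)


def mode_contributions(dmap: DiversityMap) -> dict:
    """Genome-average added coalescence rates per mode and their shares.

    BS adds 1/B(x) - 1 and sweeps add S_scaled(x) (both in units of
    1/(2 Ne)); shares are the genome means of each divided by their sum.
    Undefined (NaN, flagged) for a neutral map.
    """
    bs_mean = float(dmap.bs_rate.mean())
    cs_mean = float(dmap.cs_rate.mean())
    tot = bs_mean + cs_mean
    if tot <= 0:
        return {"bs_rate_mean": bs_mean, "cs_rate_mean": cs_mean,
                "bs_share": float("nan"), "cs_share": float("nan"),
                "flagged_neutral": True}
    return {"bs_rate_mean": bs_mean, "cs_rate_mean": cs_mean,
            "bs_share": bs_mean / tot, "cs_share": cs_mean / tot,
            "flagged_neutral": False}
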
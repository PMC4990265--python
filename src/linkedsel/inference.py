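"""Composite-likelihood evaluation and maximisation.

The probability that a random pair of sampled alleles differs at neutral
site x is modelled as

    pi(x) = pi0 u_rel(x) / (pi0 u_rel(x) + 1/B(x) + S_scaled(x)),

where pi0 = 4 Ne u-bar is the expected heterozygosity without linked
selection, B(x) the background-selection factor and S_scaled(x) the sweep
coalescence rate in units of 1/(2 Ne). Pairwise difference indicators are
treated as independent across sites and pairs, giving the composite
log-likelihood  sum_x [ n_diff log pi + n_same log(1 - pi) ].

The sweep term couples pi0 through the lineage depth, T / 2Ne =
(k_bar / 2) / pi0; the optimiser treats this dependence exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from linkedsel.genome_data import NeutralSiteTable
from linkedsel.selection_effects import BSLookup, SelectionGrid, SweepLookup

#: internal rescaling of BS weights (deleterious rates ~1e-8) for conditioning
_U_SCALE = 1e-8


@dataclass
class ModelParams:
    """pi0 plus DFE grid weights for background selection and sweeps.

    ``w_bs[g, i]`` is the deleterious mutation rate per site per generation
    assigned to grid mass t_g in BS class i; ``w_cs[k, j]`` the fraction of
    class-j substitutions that were beneficial with coefficient s_k.
    """

    pi0: float
    w_bs: np.ndarray
    w_cs: np.ndarray
    bs_classes: list[str] = field(default_factory=list)
    cs_classes: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.w_bs = np.atleast_2d(np.asarray(self.w_bs, dtype=np.float64))
        self.w_cs = np.atleast_2d(np.asarray(self.w_cs, dtype=np.float64))
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must lie in (0, 1)")
        if np.any(self.w_bs < 0) or np.any(self.w_cs < 0):
            raise ValueError("grid weights must be non-negative")
        if self.w_cs.size and np.any(self.w_cs.sum(axis=0) > 1.0 + 1e-12):
            raise ValueError("sweep weights must sum to <= 1 per class")

    @classmethod
    def neutral(cls, pi0: float, grid: SelectionGrid, bs_classes: list[str],
                cs_classes: list[str]) -> "ModelParams":
        return cls(pi0=pi0, w_bs=np.zeros((grid.n_t, len(bs_classes))),
                   w_cs=np.zeros((grid.n_s, len(cs_classes))),
                   bs_classes=list(bs_classes), cs_classes=list(cs_classes))

    def bs_class_totals(self) -> dict[str, float]:
        """Total deleterious mutation rate per BS class (sum over grid)."""
        return {c: float(self.w_bs[:, i].sum()) for i, c in enumerate(self.bs_classes)}

    def cs_class_totals(self) -> dict[str, float]:
        """Total beneficial fraction per sweep class (sum over grid)."""
        return {c: float(self.w_cs[:, j].sum()) for j, c in enumerate(self.cs_classes)}

    def to_dict(self) -> dict:
        return {"pi0": self.pi0, "w_bs": self.w_bs.tolist(),
                "w_cs": self.w_cs.tolist(), "bs_classes": self.bs_classes,
                "cs_classes": self.cs_classes}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(pi0=d["pi0"], w_bs=np.asarray(d["w_bs"]),
                   w_cs=np.asarray(d["w_cs"]), bs_classes=list(d["bs_classes"]),
                   cs_classes=list(d["cs_classes"]))


def predicted_pi(pi0, B, S_scaled, u_rel):
    """Expected neutral heterozygosity under the linked-selection model.

    pi = pi0 u_rel / (pi0 u_rel + 1/B + S_scaled); strictly increasing in
    pi0, u_rel and B, strictly decreasing in S_scaled. Always in (0, 1)
    because B <= 1 makes the denominator exceed the numerator by >= 1.
    """
    B = np.asarray(B, dtype=np.float64)
    S = np.asarray(S_scaled, dtype=np.float64)
    u = np.asarray(u_rel, dtype=np.float64)
    num = pi0 * u
    out = num / (num + 1.0 / B + S)
    return float(out) if out.ndim == 0 else out


def composite_loglik(params: ModelParams, table: NeutralSiteTable,
                     bs_lookup: BSLookup | None, sweep_lookup: SweepLookup | None,
                     k_bar: float, site_mask: np.ndarray | None = None
                     ) -> tuple[float, dict[str, float]]:
    """Composite log-likelihood over fit-masked sites (total, per-chromosome).

    Per-site contribution n_diff log pi + n_same log(1 - pi); always <= 0.
    """
    from linkedsel.selection_effects import bs_factor, sweep_rate_scaled

    mask = table.fit_mask if site_mask is None else site_mask
    B = bs_factor(params.w_bs, bs_lookup) if bs_lookup is not None else 1.0
    S = (sweep_rate_scaled(params.w_cs, sweep_lookup, params.pi0, k_bar)
         if sweep_lookup is not None else 0.0)
    pi = predicted_pi(params.pi0, np.broadcast_to(np.asarray(B, float), (len(table),)),
                      np.broadcast_to(np.asarray(S, float), (len(table),)),
                      table.u_rel)
    ll_site = np.where(mask, table.n_diff * np.log(pi)
                       + table.n_same * np.log1p(-pi), 0.0)
    per_chrom = {}
    for chrom in table.chroms():
        idx = table.chrom_slice(chrom)
        per_chrom[chrom] = float(ll_site[idx].sum())
    return float(ll_site[mask].sum()), per_chrom


def count_free_params(variant: str, bs_classes, cs_classes,
                      grid: SelectionGrid) -> int:
    """Number of scalars optimised: pi0 plus the free weight blocks.

    ``variant`` is 'bs', 'cs' or 'both'; class arguments may be lists of
    labels or integers.
    """
    n_bs = bs_classes if isinstance(bs_classes, int) else len(bs_classes)
    n_cs = cs_classes if isinstance(cs_classes, int) else len(cs_classes)
    if variant not in ("bs", "cs", "both"):
        raise ValueError(f"unknown variant {variant!r}")
    n = 1
    if variant in ("bs", "both"):
        n += grid.n_t * n_bs
    if variant in ("cs", "both"):
        n += grid.n_s * n_cs
    return n


def estimate_Ne(mean_het: float, mu_direct: float) -> float:
    """Average effective population size from mean neutral heterozygosity and
    a direct estimate of the per-site spontaneous mutation rate:
    Ne = heterozygosity / (4 mu)."""
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean heterozygosity must lie in (0, 1)")
    if not mu_direct > 0:
        raise ValueError("mutation rate must be positive")
    return mean_het / (4.0 * mu_direct)


@dataclass
class OptConfig:
    """Optimiser settings for the composite-likelihood maximisation.

    Multi-start bounded L-BFGS-B: one null start (all weights zero, pi0 at
    the observed mean scaled heterozygosity) plus ``n_starts - 1`` random
    draws from the constraint box, all seeded. Per-class sum constraints
    (sweep fractions <= 1; optional deleterious-rate bound) are enforced by
    a quadratic penalty plus a final projection.
    """

    n_starts: int = 8
    seed: int = 0
    maxiter: int = 1000
    ftol: float = 1e-12
    gtol: float = 1e-9
    pi0_bounds: tuple[float, float] = (1e-6, 0.5)
    w_bs_max_mass: float = 1e-6   # per-mass upper bound on a deleterious rate
    penalty: float = 1e5
    random_wcs_total: float = 0.7
    random_wbs_total: float = 3e-8


@dataclass
class FitResult:
    """Outcome of a composite-likelihood fit."""

    params: ModelParams
    logCL: float
    n_free_params: int
    starts: list[dict]
    variant: str
    converged: bool
    k_bar: float
    constraint_violation: float = 0.0

    def to_json(self, path=None) -> str:
        payload = {
            "variant": self.variant, "logCL": self.logCL,
            "n_free_params": self.n_free_params, "converged": self.converged,
            "k_bar": self.k_bar, "params": self.params.to_dict(),
            "constraint_violation": self.constraint_violation,
            "starts": self.starts,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(params=ModelParams.from_dict(d["params"]), logCL=d["logCL"],
                   n_free_params=d["n_free_params"], starts=d["starts"],
                   variant=d["variant"], converged=d["converged"],
                   k_bar=d["k_bar"],
                   constraint_violation=d.get("constraint_violation", 0.0))

    def weights_table(self) -> "object":
        """Human-readable weights per class x grid mass (pandas DataFrame)."""
        import pandas as pd

        rows = []
        p = self.params
        for i, c in enumerate(p.bs_classes):
            for g in range(p.w_bs.shape[0]):
                rows.append(("bs", c, g, p.w_bs[g, i]))
        for j, c in enumerate(p.cs_classes):
            for k in range(p.w_cs.shape[0]):
                rows.append(("cs", c, k, p.w_cs[k, j]))
        return pd.DataFrame(rows, columns=["mode", "cls", "grid_index", "weight"])


class _Objective:
    """Precomputed masked design for fast likelihood/gradient evaluation."""

    def __init__(self, table: NeutralSiteTable, bs_lookup, sweep_lookup,
                 k_bar: float, variant: str, mask: np.ndarray,
                 u_max: dict[str, float] | None, cfg: OptConfig):
        self.variant = variant
        self.k_bar = k_bar
        self.cfg = cfg
        self.nd = table.n_diff[mask].astype(np.float64)
        self.ns = table.n_same[mask].astype(np.float64)
        self.u = table.u_rel[mask]
        self.W = float((self.nd + self.ns).sum())
        if self.W <= 0:
            raise ValueError("no informative pairs in the fit mask")
        self.use_bs = variant in ("bs", "both") and bs_lookup is not None
        self.use_cs = variant in ("cs", "both") and sweep_lookup is not None
        if variant in ("bs", "both") and bs_lookup is None:
            raise ValueError("variant requires a BS lookup")
        if variant in ("cs", "both") and sweep_lookup is None:
            raise ValueError("variant requires a sweep lookup")
        self.bs_shape = bs_lookup.b.shape[1:] if bs_lookup is not None else (0, 0)
        self.cs_shape = sweep_lookup.s.shape[1:] if sweep_lookup is not None else (0, 0)
        self.nb = int(np.prod(self.bs_shape)) if self.use_bs else 0
        self.nc = int(np.prod(self.cs_shape)) if self.use_cs else 0
        self.Bb = (bs_lookup.b[mask].reshape(mask.sum(), -1)
                   if self.use_bs else None)
        self.Ss = (sweep_lookup.s[mask].reshape(mask.sum(), -1)
                   if self.use_cs else None)
        self.bs_classes = list(bs_lookup.classes) if bs_lookup is not None else []
        self.cs_classes = list(sweep_lookup.classes) if sweep_lookup is not None else []
        # optional per-class bound on the total deleterious rate
        self.u_max = None
        if u_max is not None and self.use_bs:
            self.u_max = np.array([u_max.get(c, np.inf) for c in self.bs_classes])

    # -- vector packing ------------------------------------------------------
    def pack(self, pi0: float, w_bs: np.ndarray, w_cs: np.ndarray) -> np.ndarray:
        parts = [np.array([pi0])]
        if self.use_bs:
            parts.append(np.asarray(w_bs, float).reshape(-1) / _U_SCALE)
        if self.use_cs:
            parts.append(np.asarray(w_cs, float).reshape(-1))
        return np.concatenate(parts)

    def unpack(self, x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        pi0 = float(x[0])
        w_bs = np.zeros(self.bs_shape)
        w_cs = np.zeros(self.cs_shape)
        off = 1
        if self.use_bs:
            w_bs = (x[off:off + self.nb] * _U_SCALE).reshape(self.bs_shape)
            off += self.nb
        if self.use_cs:
            w_cs = x[off:off + self.nc].reshape(self.cs_shape)
        return pi0, w_bs, w_cs

    def bounds(self) -> list[tuple[float, float]]:
        b = [self.cfg.pi0_bounds]
        b += [(0.0, self.cfg.w_bs_max_mass / _U_SCALE)] * self.nb
        b += [(0.0, 1.0)] * self.nc
        return b

    # -- negative normalised log-composite-likelihood + penalty -------------
    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        pi0 = x[0]
        grad = np.zeros_like(x)
        off = 1
        if self.use_bs:
            wb = x[off:off + self.nb]
            expo = self.Bb @ (wb * _U_SCALE)
            invB = np.exp(expo)
            off_b, off = off, off + self.nb
        else:
            invB = 1.0
        if self.use_cs:
            wc = x[off:off + self.nc]
            c = self.Ss @ wc
            S = (2.0 * pi0 / self.k_bar) * c
            off_c = off
        else:
            c = 0.0
            S = 0.0
        N = pi0 * self.u
        D = N + invB + S
        pi = N / D
        ll = self.nd @ np.log(pi) + self.ns @ np.log1p(-pi)
        f = -ll / self.W
        q = self.nd / pi - self.ns / (1.0 - pi)
        common = q / (D * D)
        # d(-ll)/d pi0: pi depends on pi0 directly and through the sweep rate
        grad[0] = -float((common * (invB + S) * self.u).sum()) / self.W
        if self.use_cs:
            grad[0] += float((common * N * (2.0 / self.k_bar) * c).sum()) / self.W
        if self.use_bs:
            gb = self.Bb.T @ (common * N * invB)
            grad[off_b:off_b + self.nb] = gb * _U_SCALE / self.W
        if self.use_cs:
            gc = self.Ss.T @ (common * N)
            grad[off_c:off_c + self.nc] = gc * (2.0 * pi0 / self.k_bar) / self.W
        # penalties for per-class sum constraints
        lam = self.cfg.penalty
        if self.use_cs and self.cs_shape[1] > 0:
            wcm = x[1 + self.nb:1 + self.nb + self.nc].reshape(self.cs_shape)
            viol = np.maximum(wcm.sum(axis=0) - 1.0, 0.0)
            f += lam * float((viol ** 2).sum())
            gpen = np.broadcast_to(2.0 * lam * viol, self.cs_shape)
            grad[1 + self.nb:1 + self.nb + self.nc] += gpen.reshape(-1)
        if self.use_bs and self.u_max is not None:
            wbm = (x[1:1 + self.nb] * _U_SCALE).reshape(self.bs_shape)
            viol = np.maximum(wbm.sum(axis=0) - self.u_max, 0.0) / _U_SCALE
            f += lam * float((viol ** 2).sum())
            gpen = np.broadcast_to(2.0 * lam * viol, self.bs_shape)
            grad[1:1 + self.nb] += gpen.reshape(-1)
        return f, grad

    def loglik(self, x: np.ndarray) -> float:
        pi0, w_bs, w_cs = self.unpack(x)
        invB = np.exp(self.Bb @ w_bs.reshape(-1)) if self.use_bs else 1.0
        S = ((2.0 * pi0 / self.k_bar) * (self.Ss @ w_cs.reshape(-1))
             if self.use_cs else 0.0)
        N = pi0 * self.u
        pi = N / (N + invB + S)
        return float(self.nd @ np.log(pi) + self.ns @ np.log1p(-pi))

    def project(self, x: np.ndarray) -> np.ndarray:
        """Exact projection onto the constraint set (clip + per-class rescale)."""
        x = x.copy()
        lo, hi = self.cfg.pi0_bounds
        x[0] = np.clip(x[0], lo, hi)
        x[1:] = np.maximum(x[1:], 0.0)
        if self.use_cs and self.cs_shape[1] > 0:
            wcm = x[1 + self.nb:1 + self.nb + self.nc].reshape(self.cs_shape).copy()
            sums = wcm.sum(axis=0)
            over = sums > 1.0
            if np.any(over):
                wcm[:, over] /= sums[over]
            x[1 + self.nb:1 + self.nb + self.nc] = wcm.reshape(-1)
        if self.use_bs and self.u_max is not None:
            wbm = (x[1:1 + self.nb] * _U_SCALE).reshape(self.bs_shape).copy()
            sums = wbm.sum(axis=0)
            over = sums > self.u_max
            if np.any(over):
                wbm[:, over] *= (self.u_max[over] / sums[over])
            x[1:1 + self.nb] = wbm.reshape(-1) / _U_SCALE
        return x

    def violation(self, x: np.ndarray) -> float:
        v = 0.0
        lo, hi = self.cfg.pi0_bounds
        v = max(v, lo - x[0], x[0] - hi)
        v = max(v, float(-(x[1:].min(initial=0.0))))
        if self.use_cs and self.cs_shape[1] > 0:
            wcm = x[1 + self.nb:1 + self.nb + self.nc].reshape(self.cs_shape)
            v = max(v, float(np.max(wcm.sum(axis=0) - 1.0, initial=0.0)))
        if self.use_bs and self.u_max is not None:
            wbm = (x[1:1 + self.nb] * _U_SCALE).reshape(self.bs_shape)
            v = max(v, float(np.max(wbm.sum(axis=0) - self.u_max, initial=0.0)))
        return max(v, 0.0)


def _initial_pi0(obj: _Objective, cfg: OptConfig) -> float:
    h = float((obj.nd / obj.u).sum() / obj.W)
    h = min(max(h, 1e-6), 0.49)
    return float(np.clip(h / (1.0 - h), cfg.pi0_bounds[0], cfg.pi0_bounds[1]))


def fit(table: NeutralSiteTable, bs_lookup: BSLookup | None,
        sweep_lookup: SweepLookup | None, k_bar: float, *,
        variant: str = "both", u_max: dict[str, float] | None = None,
        opt_config: OptConfig | None = None,
        site_mask: np.ndarray | None = None,
        extra_starts: list[ModelParams] | None = None) -> FitResult:
    """Maximise the composite likelihood over pi0 and the free grid weights.

    ``variant`` selects the free weight blocks ('bs', 'cs' or 'both'; the
    other block is pinned at zero). ``u_max`` optionally bounds the total
    deleterious mutation rate per BS class. ``site_mask`` overrides the
    table's fit mask (used by cross-validation); ``extra_starts`` adds warm
    starts to the multi-start schedule. Deterministic given
    ``opt_config.seed``.
    """
    cfg = opt_config or OptConfig()
    if variant not in ("bs", "cs", "both"):
        raise ValueError(f"unknown variant {variant!r}")
    mask = table.fit_mask if site_mask is None else np.asarray(site_mask, bool)
    obj = _Objective(table, bs_lookup, sweep_lookup, k_bar, variant, mask,
                     u_max, cfg)
    rng = np.random.default_rng(cfg.seed)
    pi0_init = _initial_pi0(obj, cfg)

    starts_x = [obj.pack(pi0_init, np.zeros(obj.bs_shape), np.zeros(obj.cs_shape))]
    for params in (extra_starts or []):
        starts_x.append(obj.project(obj.pack(params.pi0, params.w_bs, params.w_cs)))
    while len(starts_x) < cfg.n_starts + len(extra_starts or []):
        pi0 = float(np.clip(pi0_init * np.exp(rng.normal(0.0, 0.5)),
                            cfg.pi0_bounds[0], cfg.pi0_bounds[1]))
        w_bs = np.zeros(obj.bs_shape)
        if obj.use_bs and obj.bs_shape[1] > 0:
            raw = rng.uniform(size=obj.bs_shape)
            tot = rng.uniform(0.0, cfg.random_wbs_total, size=obj.bs_shape[1])
            w_bs = raw / raw.sum(axis=0, keepdims=True) * tot
        w_cs = np.zeros(obj.cs_shape)
        if obj.use_cs and obj.cs_shape[1] > 0:
            raw = rng.uniform(size=obj.cs_shape)
            tot = rng.uniform(0.0, cfg.random_wcs_total, size=obj.cs_shape[1])
            w_cs = raw / raw.sum(axis=0, keepdims=True) * tot
        starts_x.append(obj.pack(pi0, w_bs, w_cs))

    records, best_x, best_f = [], None, np.inf
    for x0 in starts_x:
        res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                       bounds=obj.bounds(),
                       options={"maxiter": cfg.maxiter, "ftol": cfg.ftol,
                                "gtol": cfg.gtol, "maxcor": 30})
        records.append({"x0_pi0": float(x0[0]), "fun": float(res.fun),
                        "nit": int(res.nit), "converged": bool(res.success),
                        "logCL": obj.loglik(res.x)})
        if res.fun < best_f:
            best_f, best_x = float(res.fun), res.x

    best_x = obj.project(best_x)
    pi0, w_bs, w_cs = obj.unpack(best_x)
    logCL = obj.loglik(best_x)
    params = ModelParams(pi0=pi0, w_bs=w_bs, w_cs=w_cs,
                         bs_classes=obj.bs_classes, cs_classes=obj.cs_classes)
    n_free = 1 + obj.nb + obj.nc  # pi0 plus the free weight blocks
    return FitResult(params=params, logCL=logCL, n_free_params=n_free,
                     starts=records, variant=variant,
                     converged=any(r["converged"] for r in records),
                     k_bar=k_bar, constraint_violation=obj.violation(best_x))
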
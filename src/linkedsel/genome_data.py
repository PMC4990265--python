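"""Data model and I/O for annotations, genetic maps, substitutions and polymorphism.

Coordinate convention: 0-based, half-open everywhere internally (BED native).
Genetic positions are handled in Morgans; recombination rates in cM/Mb
(1 cM/Mb == 1e-8 Morgan/bp). All tabular readers accept plain or gzipped
text (by file extension) and emit the same dialects when writing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: conversion factor: cM/Mb -> Morgan/bp
CM_PER_MB_TO_M_PER_BP = 1e-8


class ParseError(ValueError):
    """Malformed record in an input file (carries the offending line number)."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
            if line is not None:
                prefix += f":{line}"
            prefix += ": "
        super().__init__(prefix + message)


class ReferenceError_(ValueError):
    """A record refers to a chromosome absent from the genetic map."""


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    cls: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"interval must satisfy start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort and merge overlapping/adjacent intervals."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    if len(starts) == 0:
        return starts, ends
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


@dataclass
class AnnotationSet:
    """Genomic intervals grouped by annotation class (background-selection targets).

    ``intervals[cls][chrom]`` is an ``(n, 2)`` int64 array of sorted,
    non-overlapping ``[start, end)`` pairs; normalisation (sorting and merging
    within a class) happens at construction.
    """

    classes: list[str]
    intervals: dict[str, dict[str, np.ndarray]]

    @classmethod
    def from_records(cls, records: list[GenomicInterval], classes: list[str] | None = None
                     ) -> "AnnotationSet":
        if classes is None:
            classes = sorted({r.cls for r in records})
        if len(set(classes)) != len(classes):
            raise ValueError("annotation class labels must be unique")
        known = set(classes)
        for r in records:
            if r.cls not in known:
                raise ValueError(f"interval class {r.cls!r} not among declared classes")
        table: dict[str, dict[str, np.ndarray]] = {c: {} for c in classes}
        by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for r in records:
            by_key.setdefault((r.cls, r.chrom), []).append((r.start, r.end))
        for (c, chrom), pairs in by_key.items():
            s = np.array([p[0] for p in pairs], dtype=np.int64)
            e = np.array([p[1] for p in pairs], dtype=np.int64)
            s, e = _merge_intervals(s, e)
            table[c][chrom] = np.column_stack([s, e])
        return cls(classes=list(classes), intervals=table)

    def chroms(self) -> list[str]:
        out: set[str] = set()
        for per_chrom in self.intervals.values():
            out.update(per_chrom.keys())
        return sorted(out)

    def total_bp(self, cls_: str) -> int:
        tot = 0
        for arr in self.intervals.get(cls_, {}).values():
            tot += int((arr[:, 1] - arr[:, 0]).sum())
        return tot

    def n_intervals(self, cls_: str | None = None) -> int:
        classes = [cls_] if cls_ is not None else self.classes
        return sum(len(arr) for c in classes for arr in self.intervals.get(c, {}).values())


@dataclass
class SubstitutionSet:
    """Positions of lineage-specific substitutions, grouped by sweep class.

    ``positions[cls][chrom]`` is a sorted int64 array of 0-based positions,
    unique within a class.
    """

    classes: list[str]
    positions: dict[str, dict[str, np.ndarray]]

    @classmethod
    def from_records(cls, records: list[tuple[str, int, str]],
                     classes: list[str] | None = None) -> "SubstitutionSet":
        if classes is None:
            classes = sorted({r[2] for r in records})
        known = set(classes)
        by_key: dict[tuple[str, str], list[int]] = {}
        for chrom, pos, c in records:
            if c not in known:
                raise ValueError(f"substitution class {c!r} not among declared classes")
            by_key.setdefault((c, chrom), []).append(int(pos))
        table: dict[str, dict[str, np.ndarray]] = {c: {} for c in classes}
        for (c, chrom), poss in by_key.items():
            arr = np.unique(np.asarray(poss, dtype=np.int64))
            if len(arr) != len(poss):
                raise ValueError(
                    f"duplicate substitution positions in class {c!r} on {chrom}")
            table[c][chrom] = arr
        return cls(classes=list(classes), positions=table)

    def count(self, cls_: str | None = None) -> int:
        classes = [cls_] if cls_ is not None else self.classes
        return sum(len(arr) for c in classes for arr in self.positions.get(c, {}).values())

    def chroms(self) -> list[str]:
        out: set[str] = set()
        for per_chrom in self.positions.values():
            out.update(per_chrom.keys())
        return sorted(out)


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> Morgan map per chromosome.

    ``knots[chrom] = (bp, morgans)`` with bp strictly increasing and cumulative
    genetic position non-decreasing. Queries outside the mapped span are
    clamped to the terminal knots (zero rate beyond the map).
    """

    knots: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        for chrom, (bp, m) in self.knots.items():
            bp = np.asarray(bp, dtype=np.float64)
            m = np.asarray(m, dtype=np.float64)
            if len(bp) < 2:
                raise ValueError(f"map for {chrom} needs at least two knots")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map positions for {chrom} must be strictly increasing")
            if np.any(np.diff(m) < 0):
                raise ValueError(f"cumulative map for {chrom} must be non-decreasing")
            self.knots[chrom] = (bp, m)

    @classmethod
    def from_rates(cls, segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
                   ) -> "GeneticMap":
        """Build from per-interval rates: ``{chrom: (starts, ends, cM_per_Mb)}``.

        Intervals must be sorted and non-overlapping; gaps between consecutive
        intervals are bridged with zero rate.
        """
        knots = {}
        for chrom, (starts, ends, rates) in segments.items():
            starts = np.asarray(starts, dtype=np.float64)
            ends = np.asarray(ends, dtype=np.float64)
            rates = np.asarray(rates, dtype=np.float64)
            if np.any(rates < 0):
                raise ValueError(f"negative recombination rate on {chrom}")
            bp = [starts[0]]
            m = [0.0]
            for s, e, r in zip(starts, ends, rates):
                if s < bp[-1]:
                    raise ValueError(f"overlapping map intervals on {chrom}")
                if s > bp[-1]:  # gap: zero rate
                    bp.append(s)
                    m.append(m[-1])
                bp.append(e)
                m.append(m[-1] + (e - s) * r * CM_PER_MB_TO_M_PER_BP)
            knots[chrom] = (np.asarray(bp), np.asarray(m))
        return cls(knots=knots)

    def chroms(self) -> list[str]:
        return sorted(self.knots.keys())

    def span(self, chrom: str) -> tuple[float, float]:
        bp, _ = self.knots[chrom]
        return float(bp[0]), float(bp[-1])

    def cum_morgans(self, chrom: str, pos) -> np.ndarray:
        """Cumulative genetic position (Morgans) at bp position(s), interpolated."""
        if chrom not in self.knots:
            raise ReferenceError_(f"chromosome {chrom!r} absent from genetic map")
        bp, m = self.knots[chrom]
        return np.interp(np.asarray(pos, dtype=np.float64), bp, m)

    def rate_cm_per_mb(self, chrom: str, pos) -> np.ndarray:
        """Local recombination rate (cM/Mb) of the map segment containing pos."""
        if chrom not in self.knots:
            raise ReferenceError_(f"chromosome {chrom!r} absent from genetic map")
        bp, m = self.knots[chrom]
        seg_rates = np.diff(m) / np.diff(bp) / CM_PER_MB_TO_M_PER_BP
        idx = np.clip(np.searchsorted(bp, np.asarray(pos, dtype=np.float64), side="right") - 1,
                      0, len(seg_rates) - 1)
        return seg_rates[idx]


def genetic_distance(gmap: GeneticMap, chrom: str, bp1, bp2) -> np.ndarray | float:
    """Genetic distance in Morgans between two positions on one chromosome.

    Symmetric and non-negative; linear interpolation of cumulative Morgans
    between map knots. Inter-chromosomal distances are undefined by contract:
    callers must only compare positions on the same chromosome.
    """
    d = np.abs(gmap.cum_morgans(chrom, bp1) - gmap.cum_morgans(chrom, bp2))
    return float(d) if np.ndim(d) == 0 else d


@dataclass
class NeutralSiteTable:
    """Per-site neutral polymorphism summarised as pairwise-difference counts.

    Sites are sorted by (chrom, pos). ``n_diff[x]`` counts sample pairs that
    differ at x and ``n_same[x]`` pairs that are identical, so
    ``n_diff + n_same == C(n, 2)`` for n alleles with data. ``u_rel`` is the
    local relative mutation rate u(x)/u-bar, ``rec_rate`` the local cM/Mb.
    ``fit_mask``/``predict_mask`` select sites used for fitting / prediction.
    """

    chrom: np.ndarray
    pos: np.ndarray
    n_diff: np.ndarray
    n_same: np.ndarray
    u_rel: np.ndarray
    rec_rate: np.ndarray
    fit_mask: np.ndarray
    predict_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.pos)
        for name in ("chrom", "n_diff", "n_same", "u_rel", "rec_rate",
                     "fit_mask", "predict_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name} has inconsistent length")
        if np.any(self.n_diff < 0) or np.any(self.n_same < 0):
            raise ValueError("pair counts must be non-negative")
        if np.any(self.u_rel <= 0):
            raise ValueError("u_rel must be positive")

    @classmethod
    def from_arrays(cls, chrom, pos, n_diff, n_same, u_rel=None, rec_rate=None,
                    meta=None) -> "NeutralSiteTable":
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        order = np.lexsort((pos, chrom.astype(str)))
        n = len(pos)
        ones = np.ones(n, dtype=np.float64)
        return cls(
            chrom=chrom[order],
            pos=pos[order],
            n_diff=np.asarray(n_diff, dtype=np.int64)[order],
            n_same=np.asarray(n_same, dtype=np.int64)[order],
            u_rel=(ones if u_rel is None else np.asarray(u_rel, dtype=np.float64)[order]),
            rec_rate=(np.full(n, np.nan) if rec_rate is None
                      else np.asarray(rec_rate, dtype=np.float64)[order]),
            fit_mask=np.ones(n, dtype=bool),
            predict_mask=np.ones(n, dtype=bool),
            meta=dict(meta or {}),
        )

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_pairs(self) -> np.ndarray:
        return self.n_diff + self.n_same

    @property
    def het(self) -> np.ndarray:
        """Per-site heterozygosity estimate n_diff / (n_diff + n_same)."""
        tot = self.n_pairs
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_diff / tot, np.nan)

    def chroms(self) -> list[str]:
        return sorted(set(self.chrom.astype(str)))

    def chrom_slice(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom.astype(str) == chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom.astype(str), "pos": self.pos,
            "n_diff": self.n_diff, "n_same": self.n_same,
            "u_rel": self.u_rel, "rec_rate": self.rec_rate,
            "fit_mask": self.fit_mask, "predict_mask": self.predict_mask,
        })


@dataclass
class MutationProxySummary:
    """Genome-wide summaries of the mutation-rate proxy.

    u_bar: mean divergence per informative neutral site (the normaliser of
    the sliding-window proxy). k_bar: mean number of substitutions per
    neutral site on the focal lineage; sets the lineage depth via
    T / 2Ne = (k_bar / 2) / pi0.
    """

    u_bar: float
    k_bar: float
    window_size: int

    def __post_init__(self):
        if not self.u_bar > 0:
            raise ValueError("u_bar must be positive")
        if not self.k_bar > 0:
            raise ValueError("k_bar must be positive")


def pair_counts(n_alleles, derived_count) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a biallelic site to pairwise difference/identity counts.

    For n alleles of which k carry the derived (or minor) variant:
    ``n_diff = k (n - k)`` and ``n_same = C(k, 2) + C(n - k, 2)``, so the two
    always sum to C(n, 2). Scalars in, scalars out; arrays are vectorised.
    """
    n = np.asarray(n_alleles, dtype=np.int64)
    k = np.asarray(derived_count, dtype=np.int64)
    if np.any(n < 2):
        raise ValueError("pair counts require at least two alleles")
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("derived count must lie in [0, n_alleles]")
    n_diff = k * (n - k)
    n_same = n * (n - 1) // 2 - n_diff
    if np.ndim(n_alleles) == 0 and np.ndim(derived_count) == 0:
        return int(n_diff), int(n_same)
    return n_diff, n_same


def mutation_proxy(divergence: pd.DataFrame, window_size: int = 6000,
                   k_bar: float | None = None,
                   u_rel_floor: float = 1e-3,
                   ) -> tuple[pd.DataFrame, MutationProxySummary]:
    """Estimate the local relative mutation rate u(x)/u-bar from divergence.

    ``divergence`` has columns (chrom, pos, is_substitution). For every
    informative site the substitution fraction is averaged over a window of
    ``window_size`` informative sites centred on it; windows that would
    extend past a chromosome end shrink symmetrically (and are flagged in
    the ``shrunk`` column). The per-site ratio to the genome mean is then
    renormalised to have exact unit mean over sites.

    Returns the per-site table with ``u_rel`` and a MutationProxySummary.
    By default ``k_bar`` (lineage depth) equals the genome mean divergence
    of this table; pass it explicitly when lineage-specific divergence is
    estimated from a different alignment.
    """
    df = divergence.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    vals = df["is_substitution"].to_numpy(dtype=np.float64)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("is_substitution must be 0/1")
    u_bar = float(vals.mean())
    if u_bar <= 0:
        raise ValueError("divergence table contains no substitutions; u_bar would be 0")
    half = window_size // 2
    u_win = np.empty(len(df))
    shrunk = np.zeros(len(df), dtype=bool)
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(idx)
        v = vals[idx]
        n = len(v)
        if n < window_size:
            logger.warning("chromosome %s has %d < window_size=%d informative sites",
                           chrom, n, window_size)
        c = np.concatenate([[0.0], np.cumsum(v)])
        i = np.arange(n)
        # shrink symmetrically near the ends, but keep a minimum window by
        # clipping asymmetrically once the symmetric window gets degenerate
        rad_sym = np.minimum(np.minimum(half, i), n - 1 - i)
        min_rad = min(half, max(1, window_size // 8))
        rad = np.maximum(rad_sym, min_rad)
        lo = np.clip(i - rad, 0, None)
        hi = np.clip(i + rad + 1, None, n)
        u_win[idx] = (c[hi] - c[lo]) / (hi - lo)
        shrunk[idx] = rad_sym < half
    u_rel = u_win / u_bar
    n_floored = int(np.sum(u_rel < u_rel_floor))
    if n_floored:
        logger.warning("flooring u_rel at %g for %d sites", u_rel_floor, n_floored)
        u_rel = np.maximum(u_rel, u_rel_floor)
    u_rel = u_rel / u_rel.mean()  # exact unit mean under equal weighting
    out = df.copy()
    out["u_rel"] = u_rel
    out["shrunk"] = shrunk
    summary = MutationProxySummary(
        u_bar=u_bar, k_bar=(u_bar if k_bar is None else float(k_bar)),
        window_size=window_size)
    return out, summary


def mask_by_recombination(table: NeutralSiteTable, gmap: GeneticMap,
                          min_rate_fit: float = 0.75,
                          min_rate_predict: float = 0.1,
                          distal_frac: float = 0.05) -> NeutralSiteTable:
    """Set fit/predict masks from recombination rate and distal exclusion.

    The fit mask keeps sites with local rate >= ``min_rate_fit`` cM/Mb and
    outside the distal ``distal_frac`` of each chromosome arm (both ends);
    the predict mask keeps sites with rate > ``min_rate_predict`` only.
    Sites retain all fields; a new table is returned.
    """
    rate = np.empty(len(table))
    distal = np.zeros(len(table), dtype=bool)
    for chrom in table.chroms():
        idx = table.chrom_slice(chrom)
        pos = table.pos[idx]
        rate[idx] = gmap.rate_cm_per_mb(chrom, pos)
        lo, hi = gmap.span(chrom)
        margin = (hi - lo) * distal_frac
        distal[idx] = (pos < lo + margin) | (pos >= hi - margin)
    fit_mask = (rate >= min_rate_fit) & ~distal
    predict_mask = rate > min_rate_predict
    new = replace(table, rec_rate=rate, fit_mask=fit_mask, predict_mask=predict_mask,
                  meta=dict(table.meta))
    new.meta.update(mask={"min_rate_fit": min_rate_fit,
                          "min_rate_predict": min_rate_predict,
                          "distal_frac": distal_frac})
    return new


# ----------------------------------------------------------------------------
# File dialects
# ----------------------------------------------------------------------------

def _read_tsv(path, names, dtypes) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ParseError(str(exc), path=str(path)) from exc
    for col, dt in dtypes.items():
        try:
            df[col] = df[col].astype(dt)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(bad.idxmax()) + 1 if bad.any() else None
            raise ParseError(f"column {col!r} not parseable as {dt}", path=str(path),
                             line=line) from exc
    return df


def read_annotations(path, classes: list[str] | None = None) -> AnnotationSet:
    """Read BED4 (chrom, start, end, class); 0-based half-open."""
    df = _read_tsv(path, ["chrom", "start", "end", "cls"],
                   {"start": np.int64, "end": np.int64})
    bad = df["start"] >= df["end"]
    if bad.any():
        raise ParseError("interval with start >= end", path=str(path),
                         line=int(bad.idxmax()) + 1)
    records = [GenomicInterval(r.chrom, int(r.start), int(r.end), r.cls)
               for r in df.itertuples(index=False)]
    return AnnotationSet.from_records(records, classes=classes)


def write_annotations(annotations: AnnotationSet, path) -> None:
    rows = []
    for c in annotations.classes:
        for chrom, arr in sorted(annotations.intervals[c].items()):
            for s, e in arr:
                rows.append((chrom, int(s), int(e), c))
    rows.sort(key=lambda r: (r[0], r[1]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_genetic_map(path) -> GeneticMap:
    """Read a genetic map TSV.

    Two dialects, distinguished by column count:
    4 columns (chrom, start, end, cM_per_Mb) -- per-interval rates;
    3 columns (chrom, pos, cumulative_cM)    -- cumulative positions.
    """
    probe = pd.read_csv(path, sep="\t", comment="#", header=None, nrows=5)
    ncol = probe.shape[1]
    if ncol == 4:
        df = _read_tsv(path, ["chrom", "start", "end", "rate"],
                       {"start": np.int64, "end": np.int64, "rate": np.float64})
        if (df["rate"] < 0).any():
            raise ParseError("negative recombination rate", path=str(path),
                             line=int((df["rate"] < 0).idxmax()) + 1)
        segs = {}
        for chrom, g in df.groupby("chrom", sort=False):
            g = g.sort_values("start")
            segs[str(chrom)] = (g["start"].to_numpy(), g["end"].to_numpy(),
                                g["rate"].to_numpy())
        return GeneticMap.from_rates(segs)
    if ncol == 3:
        df = _read_tsv(path, ["chrom", "pos", "cum_cm"],
                       {"pos": np.int64, "cum_cm": np.float64})
        knots = {}
        for chrom, g in df.groupby("chrom", sort=False):
            g = g.sort_values("pos")
            knots[str(chrom)] = (g["pos"].to_numpy(dtype=np.float64),
                                 g["cum_cm"].to_numpy() * 0.01)
        return GeneticMap(knots=knots)
    raise ParseError(f"genetic map must have 3 or 4 columns, found {ncol}",
                     path=str(path))


def write_genetic_map(gmap: GeneticMap, path) -> None:
    """Write as per-interval (chrom, start, end, cM_per_Mb)."""
    rows = []
    for chrom in gmap.chroms():
        bp, m = gmap.knots[chrom]
        rates = np.diff(m) / np.diff(bp) / CM_PER_MB_TO_M_PER_BP
        for s, e, r in zip(bp[:-1], bp[1:], rates):
            rows.append((chrom, int(s), int(e), repr(float(r))))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_substitutions(path, classes: list[str] | None = None) -> SubstitutionSet:
    """Read TSV (chrom, pos, class), 0-based. An empty file yields an empty set."""
    try:
        df = _read_tsv(path, ["chrom", "pos", "cls"], {"pos": np.int64})
    except pd.errors.EmptyDataError:
        return SubstitutionSet(classes=list(classes or []),
                               positions={c: {} for c in (classes or [])})
    if len(df) == 0:
        return SubstitutionSet(classes=list(classes or []),
                               positions={c: {} for c in (classes or [])})
    records = [(str(r.chrom), int(r.pos), str(r.cls)) for r in df.itertuples(index=False)]
    return SubstitutionSet.from_records(records, classes=classes)


def write_substitutions(subs: SubstitutionSet, path) -> None:
    rows = []
    for c in subs.classes:
        for chrom, arr in sorted(subs.positions[c].items()):
            rows.extend((chrom, int(p), c) for p in arr)
    rows.sort(key=lambda r: (r[0], r[1]))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_polymorphism(path) -> pd.DataFrame:
    """Read TSV (chrom, pos, n_alleles, derived_count), 0-based.

    Returns a DataFrame with pair counts added; sites with fewer than two
    alleles are dropped with a warning.
    """
    df = _read_tsv(path, ["chrom", "pos", "n_alleles", "derived_count"],
                   {"pos": np.int64, "n_alleles": np.int64,
                    "derived_count": np.int64})
    bad = df["n_alleles"] < 2
    if bad.any():
        logger.warning("dropping %d sites with n_alleles < 2", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    if ((df["derived_count"] < 0) | (df["derived_count"] > df["n_alleles"])).any():
        raise ParseError("derived_count outside [0, n_alleles]", path=str(path))
    n_diff, n_same = pair_counts(df["n_alleles"].to_numpy(),
                                 df["derived_count"].to_numpy())
    df = df.assign(n_diff=n_diff, n_same=n_same)
    return df


def read_polymorphism_vcf(path, samples: list[str] | None = None) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF into the polymorphism dialect.

    Allele counts are taken over called genotypes of ``samples`` (all samples
    by default); VCF positions (1-based) are converted to 0-based.
    """
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path), samples=samples, gts012=True)
    rows = []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types)
        called = gts != 3
        n = int(2 * called.sum())
        if n < 2:
            continue
        k = int(gts[called].sum())
        rows.append((var.CHROM, var.POS - 1, n, k))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_alleles", "derived_count"])
    n_diff, n_same = pair_counts(df["n_alleles"].to_numpy(),
                                 df["derived_count"].to_numpy())
    return df.assign(n_diff=n_diff, n_same=n_same)


def write_polymorphism(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "n_alleles", "derived_count"]].to_csv(
        path, sep="\t", header=False, index=False)


def read_pair_counts(path) -> pd.DataFrame:
    """Read TSV (chrom, pos, n_diff, n_same): polymorphism already collapsed
    to pairwise difference counts (the generic form of the polymorphism
    dialect; allele counts are a special case)."""
    df = _read_tsv(path, ["chrom", "pos", "n_diff", "n_same"],
                   {"pos": np.int64, "n_diff": np.int64, "n_same": np.int64})
    if ((df["n_diff"] < 0) | (df["n_same"] < 0)).any():
        raise ParseError("pair counts must be non-negative", path=str(path))
    return df


def write_pair_counts(table: NeutralSiteTable, path) -> None:
    pd.DataFrame({"chrom": table.chrom.astype(str), "pos": table.pos,
                  "n_diff": table.n_diff, "n_same": table.n_same}
                 ).to_csv(path, sep="\t", header=False, index=False)


def read_divergence(path) -> pd.DataFrame:
    """Read TSV (chrom, pos, is_substitution in {0, 1}), 0-based."""
    df = _read_tsv(path, ["chrom", "pos", "is_substitution"],
                   {"pos": np.int64, "is_substitution": np.int64})
    if (~df["is_substitution"].isin((0, 1))).any():
        raise ParseError("is_substitution must be 0 or 1", path=str(path))
    return df


def write_divergence(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "is_substitution"]].to_csv(path, sep="\t", header=False,
                                                   index=False)


@dataclass
class ValidationReport:
    """Counts and messages produced while loading a full input bundle."""

    n_annotation_intervals: int
    n_substitutions: int
    n_polymorphic_sites: int
    n_divergence_sites: int
    chroms: list[str]
    messages: list[str] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            f"annotation intervals: {self.n_annotation_intervals}",
            f"substitutions:        {self.n_substitutions}",
            f"neutral sites:        {self.n_polymorphic_sites}",
            f"divergence sites:     {self.n_divergence_sites}",
            f"chromosomes:          {', '.join(self.chroms)}",
        ]
        lines.extend(self.messages)
        return "\n".join(lines)


def load_inputs(annotation_path, map_path, substitution_path, polymorphism_path,
                divergence_path, *, proxy_window: int = 6000,
                min_rate_fit: float = 0.75, min_rate_predict: float = 0.1,
                distal_frac: float = 0.05,
                ) -> tuple[AnnotationSet, GeneticMap, SubstitutionSet,
                           NeutralSiteTable, MutationProxySummary]:
    """Load and cross-validate the five input files.

    Checks that every chromosome referenced by annotations, substitutions or
    polymorphism exists in the genetic map, attaches the mutation-rate proxy
    (u_rel, interpolated from divergence informative sites) and local
    recombination rates to neutral sites, and applies the recombination /
    distal masks. The validation report is logged and stored under
    ``table.meta['report']``.
    """
    annotations = read_annotations(annotation_path)
    gmap = read_genetic_map(map_path)
    subs = read_substitutions(substitution_path)
    if str(polymorphism_path).endswith((".vcf", ".vcf.gz", ".bcf")):
        poly = read_polymorphism_vcf(polymorphism_path)
    else:
        poly = read_polymorphism(polymorphism_path)
    div = read_divergence(divergence_path)

    map_chroms = set(gmap.chroms())
    for label, chroms in (("annotations", annotations.chroms()),
                          ("substitutions", subs.chroms()),
                          ("polymorphism", set(poly["chrom"].astype(str))),
                          ("divergence", set(div["chrom"].astype(str)))):
        missing = set(chroms) - map_chroms
        if missing:
            raise ReferenceError_(
                f"{label} refer to chromosomes absent from the genetic map: "
                f"{sorted(missing)}")

    div_proxy, proxy = mutation_proxy(div, window_size=proxy_window)

    u_rel = np.empty(len(poly))
    for chrom, g in poly.groupby("chrom", sort=False):
        dsub = div_proxy[div_proxy["chrom"] == chrom]
        if len(dsub) == 0:
            raise ReferenceError_(f"no divergence sites on chromosome {chrom!r}")
        u_rel[g.index] = np.interp(g["pos"].to_numpy(dtype=np.float64),
                                   dsub["pos"].to_numpy(dtype=np.float64),
                                   dsub["u_rel"].to_numpy())
    table = NeutralSiteTable.from_arrays(
        poly["chrom"].to_numpy(), poly["pos"].to_numpy(),
        poly["n_diff"].to_numpy(), poly["n_same"].to_numpy(), u_rel=u_rel)
    table = mask_by_recombination(table, gmap, min_rate_fit=min_rate_fit,
                                  min_rate_predict=min_rate_predict,
                                  distal_frac=distal_frac)
    report = ValidationReport(
        n_annotation_intervals=annotations.n_intervals(),
        n_substitutions=subs.count(),
        n_polymorphic_sites=len(table),
        n_divergence_sites=len(div),
        chroms=sorted(map_chroms),
    )
    logger.info("loaded inputs:\n%s", report)
    table.meta["report"] = report
    return annotations, gmap, subs, table, proxy
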
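"""Window-based differential-methylation calling.

Each chromosome is tiled into fixed-size windows per sequence context.  A
window is testable when both samples cover at least ``min_sites`` cytosines
of that context inside it.  Read counts are pooled within each group and
compared with a two-sided Fisher exact test; a window is a DMR when the
pooled-level fold change reaches ``fc_threshold`` (hyper, higher in group B)
or its reciprocal (hypo) AND the P value is below ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .io_formats import VALID_CONTEXTS
from .methylome import MethylomeSample

#: pseudo-level added to both pooled levels before forming the fold change,
#: so windows with a zero level remain comparable
FOLD_CHANGE_EPS = 1e-6

#: relative tolerance for probability ties in the two-sided Fisher sum
_TIE_RTOL = 1e-7


@dataclass
class WindowTest:
    """One tested genomic window with pooled two-group counts."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    context: str
    n_sites_a: int
    n_sites_b: int
    meth_a: int
    unmeth_a: int
    meth_b: int
    unmeth_b: int
    level_a: float
    level_b: float
    fold_change: float
    p_value: float
    q_value: float | None = None


@dataclass
class Dmr(WindowTest):
    """A significant window; direction is relative to group B (treated)."""

    direction: Literal["hyper", "hypo"] = "hyper"

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.context}"


@dataclass
class DmrParams:
    """Tunable thresholds of the caller (defaults follow the window rule:
    >= 5 sites per sample, two-fold pooled-level change, Fisher P < 0.05)."""

    window_size: int = 1000
    step: int = 1000
    min_sites: int = 5
    fc_threshold: float = 2.0
    alpha: float = 0.05
    padjust: Literal["none", "bh"] = "none"
    contexts: Sequence[str] = VALID_CONTEXTS

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0 or self.step > self.window_size:
            raise ValueError("need 0 < step <= window_size")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.contexts) - set(VALID_CONTEXTS)
        if unknown:
            raise ValueError(f"unknown contexts {sorted(unknown)}")


@dataclass
class DmrResult:
    dmrs: list[Dmr]
    tests: list[WindowTest]
    params: DmrParams

    def summary(self) -> pd.DataFrame:
        """Per-context counts of tested windows and hyper/hypo DMRs."""
        rows = []
        for context in self.params.contexts:
            tested = sum(t.context == context for t in self.tests)
            hyper = sum(d.context == context and d.direction == "hyper" for d in self.dmrs)
            hypo = sum(d.context == context and d.direction == "hypo" for d in self.dmrs)
            rows.append(
                {"context": context, "tested_windows": tested, "hyper": hyper, "hypo": hypo}
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities, over all tables with the
    observed margins, that do not exceed the observed table's probability
    (with a small relative tolerance for floating-point ties).  Computed in
    log space so large pooled counts do not overflow.

    Degenerate margins (an empty row or column) leave a one-dimensional
    table and return 1.0.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    lo, hi = max(0, c1 - r2), min(r1, c1)
    x = np.arange(lo, hi + 1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(x + 1)
        - gammaln(r1 - x + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - x + 1)
        - gammaln(r2 - c1 + x + 1)
    )
    logp -= logsumexp(logp)  # normalise instead of subtracting log C(n, c1)
    log_obs = logp[a - lo]
    mask = logp <= log_obs + math.log1p(_TIE_RTOL)
    return float(min(1.0, math.exp(logsumexp(logp[mask]))))


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def _chrom_sizes_from_samples(
    samples: Iterable[MethylomeSample],
) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for sample in samples:
        ends = sample.df.groupby("chrom")["pos"].max() + 1
        for chrom, end in ends.items():
            sizes[chrom] = max(sizes.get(chrom, 0), int(end))
    return sizes


def make_windows(
    sample: MethylomeSample,
    window_size: int,
    step: int,
    context: str,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[WindowTest]:
    """Tile chromosomes into [k*step, k*step + window_size) windows.

    Windows are clipped at the chromosome end and emitted only when they
    contain at least one covered site of the requested context in
    ``sample``.  Returned objects are skeletons: counts/levels are zeroed
    and filled in by :func:`test_window`.
    """
    if chrom_sizes is None:
        chrom_sizes = _chrom_sizes_from_samples([sample])
    df = sample.df[(sample.df["context"] == context) & (sample.df["n_total"] > 0)]
    out: list[WindowTest] = []
    for chrom, size in chrom_sizes.items():
        pos = df.loc[df["chrom"] == chrom, "pos"].to_numpy()
        starts = np.arange(0, size, step)
        for start in starts:
            end = min(start + window_size, size)
            if np.searchsorted(pos, start) == np.searchsorted(pos, end):
                continue  # no covered site
            out.append(
                WindowTest(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    context=context,
                    n_sites_a=0,
                    n_sites_b=0,
                    meth_a=0,
                    unmeth_a=0,
                    meth_b=0,
                    unmeth_b=0,
                    level_a=float("nan"),
                    level_b=float("nan"),
                    fold_change=float("nan"),
                    p_value=float("nan"),
                )
            )
    return out


def _window_counts(
    sample: MethylomeSample, window: WindowTest
) -> tuple[int, int, int]:
    df = sample.df
    sub = df[
        (df["chrom"] == window.chrom)
        & (df["context"] == window.context)
        & (df["pos"] >= window.start)
        & (df["pos"] < window.end)
        & (df["n_total"] > 0)
    ]
    return len(sub), int(sub["n_meth"].sum()), int((sub["n_total"] - sub["n_meth"]).sum())


def pooled_fold_change(level_a: float, level_b: float) -> float:
    """(level_B + eps) / (level_A + eps); >1 means higher methylation in B."""
    return (level_b + FOLD_CHANGE_EPS) / (level_a + FOLD_CHANGE_EPS)


def test_window(
    window: WindowTest,
    a: MethylomeSample,
    b: MethylomeSample,
    min_sites: int = 5,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> WindowTest | None:
    """Fill a window skeleton with pooled counts, levels, fold change and
    Fisher P.  Returns None ("skipped") when either sample has fewer than
    ``min_sites`` covered context sites in the window, or when no reads are
    pooled at all.  ``fc_threshold`` and ``alpha`` are recorded downstream
    by :func:`call_dmrs`; they do not affect the test itself.
    """
    n_a, meth_a, unmeth_a = _window_counts(a, window)
    n_b, meth_b, unmeth_b = _window_counts(b, window)
    if n_a < min_sites or n_b < min_sites:
        return None
    if meth_a + unmeth_a == 0 or meth_b + unmeth_b == 0:
        return None
    level_a = meth_a / (meth_a + unmeth_a)
    level_b = meth_b / (meth_b + unmeth_b)
    return replace(
        window,
        n_sites_a=n_a,
        n_sites_b=n_b,
        meth_a=meth_a,
        unmeth_a=unmeth_a,
        meth_b=meth_b,
        unmeth_b=unmeth_b,
        level_a=level_a,
        level_b=level_b,
        fold_change=pooled_fold_change(level_a, level_b),
        p_value=fisher_exact_two_sided(meth_a, unmeth_a, meth_b, unmeth_b),
    )


def adjust_pvalues(
    tests: list[WindowTest], method: Literal["none", "bh"] = "none"
) -> list[WindowTest]:
    """Attach q-values in place.  ``none`` copies P; ``bh`` applies the
    Benjamini-Hochberg step-up separately within each context."""
    if method == "none":
        for t in tests:
            t.q_value = t.p_value
        return tests
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    for context in {t.context for t in tests}:
        group = [t for t in tests if t.context == context]
        m = len(group)
        order = sorted(range(m), key=lambda i: group[i].p_value)
        q = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            q = min(q, group[i].p_value * m / rank)
            group[i].q_value = q
    return tests


def _classify_direction(t: WindowTest, fc_threshold: float) -> str | None:
    if t.fold_change >= fc_threshold:
        return "hyper"
    if t.fold_change <= 1.0 / fc_threshold:
        return "hypo"
    return None


def call_dmrs(
    a: MethylomeSample,
    b: MethylomeSample,
    params: DmrParams | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> DmrResult:
    """Call DMRs between two methylomes (direction is relative to ``b``).

    Windows come from the union of covered positions in both samples; a
    window is a DMR when (q- or) P value < alpha AND the fold change passes
    the threshold in either direction.  Output is sorted by
    (context, chrom, start).
    """
    if params is None:
        params = DmrParams()
    if chrom_sizes is None:
        chrom_sizes = _chrom_sizes_from_samples([a, b])

    tests: list[WindowTest] = []
    for context in params.contexts:
        tests.extend(
            _test_context_windows(a, b, context, params, chrom_sizes)
        )
    adjust_pvalues(tests, params.padjust)

    dmrs: list[Dmr] = []
    for t in tests:
        if t.q_value is None or t.q_value >= params.alpha:
            continue
        direction = _classify_direction(t, params.fc_threshold)
        if direction is None:
            continue
        dmrs.append(Dmr(**t.__dict__, direction=direction))
    key = lambda w: (w.context, w.chrom, w.start)
    tests.sort(key=key)
    dmrs.sort(key=key)
    return DmrResult(dmrs=dmrs, tests=tests, params=params)


def _test_context_windows(
    a: MethylomeSample,
    b: MethylomeSample,
    context: str,
    params: DmrParams,
    chrom_sizes: Mapping[str, int],
) -> list[WindowTest]:
    """Vectorised window testing for one context (cumulative-sum scan)."""
    out: list[WindowTest] = []
    for chrom, size in chrom_sizes.items():
        cols = {}
        for name, sample in (("a", a), ("b", b)):
            df = sample.df
            sub = df[
                (df["chrom"] == chrom)
                & (df["context"] == context)
                & (df["n_total"] > 0)
            ]
            pos = sub["pos"].to_numpy()
            cols[name] = (
                pos,
                np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())]),
                np.concatenate([[0], np.cumsum(sub["n_total"].to_numpy())]),
            )
        starts = np.arange(0, size, params.step)
        ends = np.minimum(starts + params.window_size, size)
        stats = {}
        for name in ("a", "b"):
            pos, cmeth, ctot = cols[name]
            lo = np.searchsorted(pos, starts)
            hi = np.searchsorted(pos, ends)
            stats[name] = (
                hi - lo,
                cmeth[hi] - cmeth[lo],
                ctot[hi] - ctot[lo],
            )
        n_a, meth_a, tot_a = stats["a"]
        n_b, meth_b, tot_b = stats["b"]
        testable = (
            (n_a >= params.min_sites)
            & (n_b >= params.min_sites)
            & (tot_a > 0)
            & (tot_b > 0)
        )
        for i in np.flatnonzero(testable):
            ma, ua = int(meth_a[i]), int(tot_a[i] - meth_a[i])
            mb, ub = int(meth_b[i]), int(tot_b[i] - meth_b[i])
            level_a = ma / (ma + ua)
            level_b = mb / (mb + ub)
            out.append(
                WindowTest(
                    chrom=chrom,
                    start=int(starts[i]),
                    end=int(ends[i]),
                    context=context,
                    n_sites_a=int(n_a[i]),
                    n_sites_b=int(n_b[i]),
                    meth_a=ma,
                    unmeth_a=ua,
                    meth_b=mb,
                    unmeth_b=ub,
                    level_a=level_a,
                    level_b=level_b,
                    fold_change=pooled_fold_change(level_a, level_b),
                    p_value=fisher_exact_two_sided(ma, ua, mb, ub),
                )
            )
    return out


def merge_adjacent_dmrs(dmrs: Sequence[Dmr], max_gap_windows: int = 1) -> list[Dmr]:
    """Optional post-process: merge same-direction, same-context DMRs whose
    windows are separated by at most ``max_gap_windows`` window lengths.
    Pooled counts are summed; the smallest P of the merged run is kept."""
    merged: list[Dmr] = []
    for d in sorted(dmrs, key=lambda x: (x.context, x.direction, x.chrom, x.start)):
        if merged:
            last = merged[-1]
            width = last.end - last.start
            same = (
                last.context == d.context
                and last.direction == d.direction
                and last.chrom == d.chrom
                and d.start - last.end <= max_gap_windows * width
            )
            if same:
                last.end = d.end
                last.n_sites_a += d.n_sites_a
                last.n_sites_b += d.n_sites_b
                last.meth_a += d.meth_a
                last.unmeth_a += d.unmeth_a
                last.meth_b += d.meth_b
                last.unmeth_b += d.unmeth_b
                last.level_a = last.meth_a / (last.meth_a + last.unmeth_a)
                last.level_b = last.meth_b / (last.meth_b + last.unmeth_b)
                last.fold_change = pooled_fold_change(last.level_a, last.level_b)
                last.p_value = min(last.p_value, d.p_value)
                continue
        merged.append(replace(d))
    return merged
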
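"""Correlation mapping between characterizations.

The workflow mirrors the analysis stage of the pipeline: screen each
series for normality (one-sample Kolmogorov-Smirnov), transform skewed
series with the one-parameter Box-Cox transform, compute pairwise
Spearman rank correlations, and flag edges significant at p < 0.001
with |ρ| > 0.5, tiered by their relation to a designated reference
node (the evaluation lever): *primary* edges touch the reference,
*secondary* edges join two nodes that are each significantly linked to
the reference.  Because Spearman correlation is rank-based, a strictly
monotone Box-Cox transform leaves ρ unchanged — the transform matters
only for the normality screen; it is kept for fidelity to the
documented procedure.

Channel delays (GSR ~2 s, heart ~6.5 s, blink ~4.65 s behind the
lever) are estimated by lagged cross-correlation of rank-transformed
series.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from stressense.series import ParameterSeries

SIG_P = 0.001
SIG_RHO = 0.5


@dataclass
class BoxCoxParams:
    lmbda: float
    shift: float = 0.0


@dataclass
class Edge:
    a: str
    b: str
    rho: float
    p: float
    lag_s: float = 0.0
    significant: bool = False
    tier: str = "none"


@dataclass
class CorrelationMap:
    nodes: list[str]
    edges: list[Edge]
    reference: str | None = None

    def edge(self, a: str, b: str) -> Edge:
        for e in self.edges:
            if {e.a, e.b} == {a, b}:
                return e
        raise KeyError(f"no edge ({a}, {b})")

    def significant_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.significant]


@dataclass
class DelayEstimate:
    lag_s: float
    peak_corr: float
    confident: bool


def ks_normality(x: ParameterSeries | np.ndarray) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean/SD."""
    v = x.dropna().values if isinstance(x, ParameterSeries) else np.asarray(x, float)
    v = v[np.isfinite(v)]
    if v.size < 20:
        raise ValueError(f"ks_normality requires n >= 20 (got {v.size})")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("ks_normality: constant input is degenerate")
    stat, p = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(stat), float(p)


def boxcox_transform(
    x: ParameterSeries,
    lmbda: float | str = "mle",
    allow_shift: bool = True,
) -> tuple[ParameterSeries, BoxCoxParams]:
    """One-parameter Box-Cox transform.

    ``yt = (y**λ − 1)/λ`` for λ ≠ 0 and ``yt = log(y)`` for λ = 0.
    ``lmbda="mle"`` picks λ maximizing the Box-Cox profile
    log-likelihood over a grid on [−3, 3].  Nonpositive inputs are
    shifted to positive (recorded in the returned params) when
    ``allow_shift``; otherwise they are an error.
    """
    v = x.values.astype(float)
    finite = np.isfinite(v)
    shift = 0.0
    vmin = np.min(v[finite])
    if vmin <= 0:
        if not allow_shift:
            raise ValueError("boxcox_transform: nonpositive values and shifting disallowed")
        span = np.max(v[finite]) - vmin
        shift = -vmin + max(1e-6, 1e-3 * span)
    y = v + shift
    yf = y[finite]
    if lmbda == "mle":
        grid = np.linspace(-3, 3, 601)
        ll = [stats.boxcox_llf(l, yf) for l in grid]
        lam = float(grid[int(np.argmax(ll))])
    else:
        lam = float(lmbda)
    out = np.full_like(v, np.nan)
    if lam == 0.0:
        out[finite] = np.log(yf)
    else:
        out[finite] = (yf ** lam - 1.0) / lam
    return (
        ParameterSeries(x.name, x.timestamps, out, dict(x.meta)),
        BoxCoxParams(lmbda=lam, shift=shift),
    )


def _spearman(a: np.ndarray, b: np.ndarray, perm_seed: int = 0) -> tuple[float, float]:
    """Spearman rho with a t-approximation p for n > 30 and a seeded
    permutation p for small samples."""
    n = a.size
    rho, p = stats.spearmanr(a, b)
    if n <= 30:
        rng = np.random.default_rng(perm_seed)
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        n_perm = 5000
        count = 0
        for _ in range(n_perm):
            r, _ = stats.pearsonr(ra, rng.permutation(rb))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    return float(rho), float(p)


def spearman_map(
    series: dict[str, ParameterSeries],
    reference: str | None = None,
    lags: dict[tuple[str, str], float] | str | None = None,
    max_lag_s: float = 10.0,
) -> CorrelationMap:
    """Pairwise Spearman correlation map with significance tiers.

    All series must share one grid.  A per-pair lag (seconds, positive
    = second series trails the first) is applied before correlating to
    compensate physiological response delays; ``lags="auto"``
    estimates each pair's lag by rank cross-correlation within
    ``±max_lag_s``.  An edge is significant iff p < 0.001 and
    |ρ| > 0.5.
    """
    if len(series) < 2:
        raise ValueError("spearman_map needs at least 2 series")
    names = list(series)
    edges: list[Edge] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = series[a], series[b]
            va, vb = sa.values, sb.values
            lag = 0.0
            if lags == "auto":
                both = np.isfinite(va) & np.isfinite(vb)
                if both.sum() >= 30 and np.ptp(va[both]) > 0 and np.ptp(vb[both]) > 0:
                    lag = estimate_delay(sa, sb, max_lag_s).lag_s
            elif lags:
                lag = lags.get((a, b), -lags.get((b, a), 0.0))
            k = 0
            if lag:
                dt = float(np.median(np.diff(sa.timestamps)))
                k = int(round(lag / dt))
            if k > 0:
                va, vb = va[:-k], vb[k:]
            elif k < 0:
                va, vb = va[-k:], vb[:k]
            m = np.isfinite(va) & np.isfinite(vb)
            if m.sum() < 30:
                raise ValueError(f"pair ({a}, {b}): overlapping n < 30")
            rho, p = _spearman(va[m], vb[m])
            sig = (p < SIG_P) and (abs(rho) > SIG_RHO)
            edges.append(Edge(a, b, rho, p, lag, sig))
    if reference is not None:
        linked = {
            n for e in edges if e.significant and reference in (e.a, e.b)
            for n in (e.a, e.b) if n != reference
        }
        for e in edges:
            if not e.significant:
                continue
            if reference in (e.a, e.b):
                e.tier = "primary"
            elif e.a in linked and e.b in linked:
                e.tier = "secondary"
    return CorrelationMap(names, edges, reference)


def estimate_delay(a: ParameterSeries, b: ParameterSeries, max_lag_s: float) -> DelayEstimate:
    """Lag of ``b`` behind ``a`` by rank cross-correlation.

    Positive ``lag_s`` means ``b`` trails ``a``.  Confident iff the
    peak rank correlation exceeds 0.5.
    """
    t = a.timestamps
    duration = t[-1] - t[0]
    if max_lag_s >= duration / 4:
        raise ValueError("max_lag_s must be < duration/4")
    dt = float(np.median(np.diff(t)))
    max_k = int(round(max_lag_s / dt))
    m = np.isfinite(a.values) & np.isfinite(b.values)
    ra = stats.rankdata(a.values[m]).astype(float)
    rb = stats.rankdata(b.values[m]).astype(float)
    ra -= ra.mean()
    rb -= rb.mean()
    best_k, best_c = 0, -np.inf
    n = ra.size
    for k in range(-max_k, max_k + 1):
        if k >= 0:
            x, y = ra[: n - k], rb[k:]
        else:
            x, y = ra[-k:], rb[: n + k]
        denom = np.sqrt((x * x).sum() * (y * y).sum())
        c = (x * y).sum() / denom if denom > 0 else 0.0
        if c > best_c:
            best_c, best_k = c, k
    return DelayEstimate(best_k * dt, float(best_c), bool(best_c > 0.5))


def render_map(cmap: CorrelationMap, out: str | Path | None = None) -> list[dict]:
    """Edge list as JSON-serializable records; optionally written to
    ``out`` (.json always; .png additionally draws the graph with line
    width proportional to |ρ| and solid/dashed by significance)."""
    records = [asdict(e) for e in cmap.edges]
    payload = {"nodes": cmap.nodes, "reference": cmap.reference, "edges": records}
    if out is not None:
        out = Path(out)
        if out.suffix == ".png":
            _draw(cmap, out)
        else:
            out.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return records


def map_from_json(path: str | Path) -> CorrelationMap:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    edges = [Edge(**e) for e in payload["edges"]]
    return CorrelationMap(payload["nodes"], edges, payload.get("reference"))


def _draw(cmap: CorrelationMap, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(cmap.nodes)
    angles = 2 * np.pi * np.arange(n) / n
    pos = {name: (np.cos(a), np.sin(a)) for name, a in zip(cmap.nodes, angles)}
    fig, ax = plt.subplots(figsize=(6, 6))
    for e in cmap.edges:
        (x0, y0), (x1, y1) = pos[e.a], pos[e.b]
        ax.plot([x0, x1], [y0, y1],
                lw=0.5 + 4 * abs(e.rho),
                ls="-" if e.significant else "--",
                color={"primary": "red", "secondary": "blue"}.get(e.tier, "0.7"))
    for name, (x, y) in pos.items():
        ax.text(x * 1.1, y * 1.1, name, ha="center", va="center")
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.axis("off")
    fig.savefig(out, dpi=120)
    plt.close(fig)
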
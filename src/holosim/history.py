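"""Reaction-history analysis: edge-flux accounting and preferred pathways.

Every reaction occurrence in the event log carries an edge label (the
reaction family, e.g. ``C1~ca``, ``K~N0C2``, ``KN2C2~p``), a direction
(+1 binding / flag set, -1 unbinding) and the source vertex (the CaM state
the forward arrow leaves from, e.g. ``N0C2`` or ``KN0C2``).  Accumulating
the *net* occurrences (bindings minus unbindings) of each edge in 10 ms
bins turns the log into a flux picture of the network: a negative series
means unbinding dominates on that edge.

The network has two layers: Layer 1 holds the reactions of free CaM
(``Nx~ca``, ``Cx~ca`` and the entry edges ``K~NxCy`` / ``Kp~NxCy``),
Layer 2 the reactions of CaMKII-bound CaM (``KNx~ca``, ``KCx~ca``,
``KNxCy~p``).  The preferred pathway is the greedy walk that leaves each
vertex along the outgoing edge with the largest final cumulative net count,
terminating at a phosphorylation edge or on a revisit; exact ties are
reported, never silently broken.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "accumulate",
    "classify_edge",
    "edge_successor",
    "preferred_path",
    "PathwaySummary",
    "species_ledger_residual",
]

_CA_EDGE = re.compile(r"^(Kp|K)?([NC][12])~ca$")
_BIND_EDGE = re.compile(r"^(Kp|K)~(N[0-2]C[0-2])$")
_PHOS_EDGE = re.compile(r"^K(N[0-2]C[0-2])~p$")


def classify_edge(label: str) -> tuple[int, str]:
    """(layer, reaction family) of an edge label.

    Layer 1: free-CaM edges (``Nx~ca``, ``Cx~ca``, ``K~NxCy``, ``Kp~NxCy``);
    Layer 2: bound-CaM edges (``KNx~ca``, ``KCx~ca``, ``KNxCy~p``).
    Raises ``KeyError`` for labels outside the network vocabulary.
    """
    m = _CA_EDGE.match(label)
    if m:
        prefix, site = m.group(1), m.group(2)
        if prefix is None:
            return 1, f"{site[0]}x~ca"
        return 2, f"{prefix}{site[0]}x~ca"
    m = _BIND_EDGE.match(label)
    if m:
        return 1, f"{m.group(1)}~NxCy"
    m = _PHOS_EDGE.match(label)
    if m:
        return 2, "KNxCy~p"
    raise KeyError(f"unknown edge label {label!r}")


def accumulate(events, bin_width: float = 0.01, t0: float = 0.0,
               t1: float | None = None, trial: int = 0) -> pd.DataFrame:
    """Cumulative net occurrence series for every (vertex, edge) pair.

    ``events`` is an iterable of EventRecords (or a list of such iterables,
    one per trial; trials are summed, as when pooling replicate runs).
    Returns a tidy frame with columns ``time_bin, vertex, edge, layer,
    net, cumulative_net, trial``.  An empty log yields an empty frame.
    """
    if events and not hasattr(events[0], "time"):
        frames = [accumulate(ev, bin_width, t0, t1, trial=i)
                  for i, ev in enumerate(events)]
        frames = [f for f in frames if len(f)]
        if not frames:
            return _empty_frame()
        df = pd.concat(frames, ignore_index=True)
        pooled = (df.groupby(["time_bin", "vertex", "edge", "layer"],
                             as_index=False)["net"].sum())
        pooled = pooled.sort_values(["vertex", "edge", "time_bin"])
        pooled["cumulative_net"] = pooled.groupby(["vertex", "edge"])["net"].cumsum()
        pooled["trial"] = -1  # pooled over trials
        return pooled.reset_index(drop=True)

    if not events:
        return _empty_frame()
    times = np.array([e.time for e in events])
    if t1 is None:
        t1 = float(times.max()) + bin_width
    keep = (times >= t0) & (times <= t1)
    rows = [(e.time, e.vertex or "", e.label, e.direction)
            for e, k in zip(events, keep) if k]
    if not rows:
        return _empty_frame()
    df = pd.DataFrame(rows, columns=["time", "vertex", "edge", "direction"])
    n_bins = int(np.ceil((t1 - t0) / bin_width))
    df["time_bin"] = t0 + (np.minimum(
        ((df["time"] - t0) / bin_width).astype(int), n_bins - 1) + 1) * bin_width
    grouped = (df.groupby(["time_bin", "vertex", "edge"], as_index=False)
               ["direction"].sum().rename(columns={"direction": "net"}))
    # complete the bin grid per edge so cumulative series are well defined
    bins = t0 + bin_width * np.arange(1, n_bins + 1)
    out = []
    for (vertex, edge), sub in grouped.groupby(["vertex", "edge"]):
        series = sub.set_index("time_bin")["net"].reindex(bins, fill_value=0)
        layer = _safe_layer(edge)
        out.append(pd.DataFrame({
            "time_bin": bins, "vertex": vertex, "edge": edge,
            "layer": layer, "net": series.values,
            "cumulative_net": series.cumsum().values, "trial": trial}))
    return pd.concat(out, ignore_index=True)


def _safe_layer(edge: str) -> int:
    try:
        return classify_edge(edge)[0]
    except KeyError:
        return 0


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["time_bin", "vertex", "edge", "layer",
                                 "net", "cumulative_net", "trial"])


def edge_successor(vertex: str, label: str) -> str | None:
    """The vertex an edge's forward direction leads to (None = terminal)."""
    m = _PHOS_EDGE.match(label)
    if m:
        return None
    m = _BIND_EDGE.match(label)
    if m:
        return f"{m.group(1)}{m.group(2)}"
    m = _CA_EDGE.match(label)
    if m:
        prefix = m.group(1) or ""
        site = m.group(2)
        core = vertex[len(prefix):] if prefix and vertex.startswith(prefix) else vertex
        n, c = int(core[1]), int(core[3])
        if site[0] == "N":
            n += 1
        else:
            c += 1
        return f"{prefix}N{n}C{c}"
    raise KeyError(f"unknown edge label {label!r}")


@dataclass
class PathwaySummary:
    """Greedy preferred path plus the per-vertex edge ranking."""

    start: str
    vertices: list = field(default_factory=list)
    edges: list = field(default_factory=list)
    ranking: dict = field(default_factory=dict)  # vertex -> [(edge, final net)]
    ties: list = field(default_factory=list)     # (vertex, [tied edges])
    diagnostic: str = ""


def preferred_path(edge_df: pd.DataFrame, start: str = "N0C0") -> PathwaySummary:
    """Extract the preferred pathway from accumulated edge series.

    At each vertex the outgoing edge with the largest final cumulative net
    count is taken; the walk stops at a phosphorylation edge, on a revisit,
    or at a vertex with no recorded outgoing edge.  Exact ties stop the walk
    and are reported.
    """
    summary = PathwaySummary(start=start)
    if edge_df.empty or (edge_df["cumulative_net"] == 0).all():
        summary.diagnostic = "no net flux recorded"
        return summary
    finals = (edge_df.sort_values("time_bin")
              .groupby(["vertex", "edge"], as_index=False)
              .agg(final=("cumulative_net", "last")))
    by_vertex: dict[str, list] = {}
    for row in finals.itertuples():
        by_vertex.setdefault(row.vertex, []).append((row.edge, float(row.final)))
    for v, lst in by_vertex.items():
        lst.sort(key=lambda t: (-t[1], t[0]))
    summary.ranking = by_vertex

    v = start
    seen = {start}
    summary.vertices.append(start)
    while True:
        outgoing = by_vertex.get(v)
        if not outgoing:
            summary.diagnostic = f"no outgoing flux from {v}"
            break
        best = outgoing[0]
        tied = [e for e, f in outgoing if f == best[1]]
        if len(tied) > 1:
            summary.ties.append((v, tied))
            summary.diagnostic = f"tie at {v}: {tied}"
            break
        summary.edges.append(best[0])
        nxt = edge_successor(v, best[0])
        if nxt is None:  # phosphorylation: terminal
            break
        if nxt in seen:
            summary.diagnostic = f"revisit of {nxt}"
            break
        seen.add(nxt)
        summary.vertices.append(nxt)
        v = nxt
    return summary


def species_ledger_residual(edge_df: pd.DataFrame, counts: pd.DataFrame,
                            initial: dict, vertices: list) -> float:
    """Exact structural check tying the event log to the species counts.

    For each listed vertex and each bin boundary:
    initial + sum(inflow edge nets) - sum(outflow edge nets) must equal the
    recorded count.  Returns the maximum absolute residual (0 when the log
    and the state agree exactly).
    """
    if edge_df.empty:
        return 0.0
    worst = 0.0
    bins = np.sort(edge_df["time_bin"].unique())
    finals = edge_df.pivot_table(index="time_bin", columns=["vertex", "edge"],
                                 values="cumulative_net", aggfunc="last")
    finals = finals.reindex(bins).ffill().fillna(0.0)
    for species in vertices:
        flow = np.zeros(len(bins))
        for (vertex, edge) in finals.columns:
            try:
                succ = edge_successor(vertex, edge)
            except KeyError:
                continue
            series = finals[(vertex, edge)].values
            if vertex == species:
                flow -= series
            if succ == species:
                flow += series
        expect = initial.get(species, 0) + flow
        # compare at the recorded times closest to each bin boundary
        t_rec = counts["time"].values
        for t, e in zip(bins, expect):
            i = int(np.argmin(np.abs(t_rec - t)))
            if abs(t_rec[i] - t) < 1e-9:
                worst = max(worst, abs(float(counts[species].values[i]) - e))
    return worst
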
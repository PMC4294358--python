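"""Hypergeometric over-connectivity of network hubs to a DE gene set.

For each hub with at least one outgoing target, the number of differentially
expressed targets (``Actual``) is compared with its expectation under
hypergeometric sampling of the ``n`` DE genes recognized in the network out
of the ``N``-node universe, given the hub's ``R`` targets:

    Expected = n*R/N
    variance = n * (R/N) * (1 - R/N) * (N - n) / (N - 1)
    Ratio    = Actual / Expected
    z        = (Actual - Expected) / sqrt(variance)

and a one-sided tail probability P(X >= Actual) (or P(X <= Actual) when z is
negative). Hubs with more DE targets than expected are "over-connected":
they have larger than expected functional input into the DE response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_fdr_bh
from .network import InteractionNetwork

CONN_COLUMNS = ["hub", "class", "FC", "Actual", "n", "R", "N",
                "Expected", "Ratio", "z-score", "p-value"]


@dataclass
class DESet:
    """Significant genes with their regulation direction."""

    genes: set[str]
    direction_of: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.direction_of) != self.genes:
            raise ValueError("direction_of must be defined exactly on genes")


def de_set_from_table(de: pd.DataFrame) -> DESet:
    """Build a DESet from a DE table's significant rows."""
    sig = de[de["significant"]]
    return DESet(
        set(sig["gene_id"]),
        dict(zip(sig["gene_id"], sig["direction"])),
    )


@dataclass
class ConnectivityRecord:
    """One hub's over-connectivity row (supplementary-table schema)."""

    hub: str
    hub_class: str
    fc: float | None       # hub's own fold change; None if unmeasured
    actual: int
    n: int                 # DE genes recognized in the network
    r: int                 # hub out-degree (distinct targets)
    n_universe: int        # network size N
    expected: float
    ratio: float | None    # None when expected == 0
    z: float | None        # None when variance == 0 (flagged, not ranked)
    p: float
    p_adj: float | None = None


def count_connectivity(net: InteractionNetwork, hub: str, de: DESet,
                       *, undirected: bool = False) -> tuple[int, int, int, int]:
    """(actual, n, r, N) for one hub.

    DE genes absent from the network are not recognized and do not count
    toward ``n``. By default ``r`` counts distinct outgoing targets; with
    ``undirected`` it counts neighbors in either direction.
    """
    targets = (net.neighbors_any_direction(hub) if undirected
               else net.out_targets(hub))
    nodes = net.nodes
    de_in_net = de.genes & nodes
    return (len(targets & de_in_net), len(de_in_net), len(targets),
            net.n_universe)


def hypergeom_mean_var(n: int, r: int, n_universe: int) -> tuple[float, float]:
    """Mean n*R/N and variance of the hypergeometric count of DE targets."""
    N = n_universe
    if N < 1:
        raise ValueError("universe size must be >= 1")
    if not (0 <= n <= N and 0 <= r <= N):
        raise ValueError(f"inconsistent counts: n={n}, r={r}, N={N}")
    expected = n * r / N
    if N < 2:
        return expected, 0.0
    variance = n * (r / N) * (1.0 - r / N) * (N - n) / (N - 1)
    return expected, variance


def connectivity_z(actual: int, expected: float, variance: float) -> float | None:
    """(Actual - Expected)/sqrt(variance); None (undefined) when variance is 0."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    if variance == 0:
        return None
    return (actual - expected) / math.sqrt(variance)


def hypergeom_tail_p(actual, n, r, n_universe, side: str = "upper"):
    """One-sided hypergeometric tail probability; accepts scalars or arrays.

    ``upper``: P(X >= actual); ``lower``: P(X <= actual), where X is the
    number of DE genes among the hub's targets under uniform sampling of the
    ``n`` DE genes from the ``N``-node universe.
    """
    if side not in ("upper", "lower"):
        raise ValueError(f"side must be 'upper' or 'lower', got {side!r}")
    actual = np.asarray(actual)
    n = np.asarray(n)
    r = np.asarray(r)
    N = np.asarray(n_universe)
    lo = np.maximum(0, n + r - N)
    hi = np.minimum(n, r)
    if np.any((actual < lo) | (actual > hi)):
        raise ValueError("actual outside the hypergeometric support")
    if side == "upper":
        p = stats.hypergeom.sf(actual - 1, N, r, n)
    else:
        p = stats.hypergeom.cdf(actual, N, r, n)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if p.ndim == 0 else p


def analyze_interactome(net: InteractionNetwork, de: DESet,
                        de_table: pd.DataFrame | None = None,
                        *, undirected: bool = False,
                        bh: bool = False) -> list[ConnectivityRecord]:
    """Score every hub with R >= 1 for over-connectivity to the DE set.

    Hub fold changes are copied from ``de_table`` when the hub was measured.
    Records with zero variance carry a null z and are excluded from ranking
    downstream. With ``bh``, BH-adjusted p-values are added across hubs.
    """
    if net.n_universe == 0:
        raise ValueError("empty network")
    fc_of: dict[str, float] = {}
    if de_table is not None:
        fc_of = dict(zip(de_table["gene_id"], de_table["fc"]))
    records: list[ConnectivityRecord] = []
    for hub in sorted(net.nodes):
        actual, n, r, N = count_connectivity(net, hub, de, undirected=undirected)
        if r == 0:
            continue
        expected, variance = hypergeom_mean_var(n, r, N)
        z = connectivity_z(actual, expected, variance)
        side = "upper" if (z is None or z >= 0) else "lower"
        p = hypergeom_tail_p(actual, n, r, N, side=side)
        ratio = actual / expected if expected > 0 else None
        records.append(ConnectivityRecord(
            hub=hub, hub_class=net.node_class(hub), fc=fc_of.get(hub),
            actual=actual, n=n, r=r, n_universe=N,
            expected=expected, ratio=ratio, z=z, p=p,
        ))
    if bh and records:
        adjusted = adjust_fdr_bh(np.array([rec.p for rec in records]))
        for rec, pa in zip(records, adjusted):
            rec.p_adj = float(pa)
    return records


def records_to_frame(records: list[ConnectivityRecord]) -> pd.DataFrame:
    """Connectivity records as a table matching the supplementary schema."""
    df = pd.DataFrame({
        "hub": [r.hub for r in records],
        "class": [r.hub_class for r in records],
        "FC": [r.fc for r in records],
        "Actual": [r.actual for r in records],
        "n": [r.n for r in records],
        "R": [r.r for r in records],
        "N": [r.n_universe for r in records],
        "Expected": [r.expected for r in records],
        "Ratio": [r.ratio for r in records],
        "z-score": [r.z for r in records],
        "p-value": [r.p for r in records],
    })
    if any(r.p_adj is not None for r in records):
        df["p-adjusted"] = [r.p_adj for r in records]
    return df


def write_connectivity(records: list[ConnectivityRecord],
                       out_path: str | Path) -> None:
    records_to_frame(records).to_csv(out_path, sep="\t", index=False)


def read_connectivity(path: str | Path) -> list[ConnectivityRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"hub": str})
    missing = [c for c in CONN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing connectivity columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        records.append(ConnectivityRecord(
            hub=d["hub"], hub_class=d["class"],
            fc=None if pd.isna(d["FC"]) else float(d["FC"]),
            actual=int(d["Actual"]), n=int(d["n"]), r=int(d["R"]),
            n_universe=int(d["N"]), expected=float(d["Expected"]),
            ratio=None if pd.isna(d["Ratio"]) else float(d["Ratio"]),
            z=None if pd.isna(d["z-score"]) else float(d["z-score"]),
            p=float(d["p-value"]),
            p_adj=(None if "p-adjusted" not in d or pd.isna(d["p-adjusted"])
                   else float(d["p-adjusted"])),
        ))
    return records
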
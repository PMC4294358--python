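"""Class-stratified z-score rankings, bar plots, and inhibitor screening.

Significantly over-connected hubs (one-sided p below the gate) of a given
molecular class are aligned by descending z-score; ranked kinases and
proteases are then joined against a table of pharmacological inhibitors to
nominate compounds targeting the most over-connected druggable hubs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .connectivity import ConnectivityRecord
from .network import CLASS_TOKENS, InteractionNetwork

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = ["hub", "class", "z", "direction", "compound", "annotation"]


@dataclass
class ClassRanking:
    """Hubs of one class passing the p gate, sorted by (z desc, p asc, hub)."""

    class_token: str
    rows: list[ConnectivityRecord]
    alpha_gate: float


def rank_by_class(records: list[ConnectivityRecord],
                  cls: str, alpha: float = 0.05) -> ClassRanking:
    """Filter records to class ``cls`` with defined z and p <= alpha, sorted.

    The sort is total: z descending, then p ascending, then hub name, so the
    ranking is invariant to the input order of the records.
    """
    if cls not in CLASS_TOKENS:
        raise ValueError(f"unknown class token {cls!r}; expected one of {CLASS_TOKENS}")
    rows = [r for r in records
            if r.hub_class == cls and r.z is not None and r.p <= alpha]
    rows.sort(key=lambda r: (-r.z, r.p, r.hub))
    return ClassRanking(cls, rows, alpha)


def ranking_to_frame(ranking: ClassRanking) -> pd.DataFrame:
    return pd.DataFrame({
        "hub": [r.hub for r in ranking.rows],
        "class": [r.hub_class for r in ranking.rows],
        "z-score": [r.z for r in ranking.rows],
        "p-value": [r.p for r in ranking.rows],
    })


def plot_ranking(ranking: ClassRanking, out_path: str | Path,
                 top: int | None = None) -> Path | None:
    """Horizontal bar chart of z-scores, best hub on top.

    Alongside the image a TSV "data sidecar" (``<out>.tsv``) is written with
    the plotted numbers, so figure content is testable and reproducible
    byte-for-byte without image comparison. Returns the image path, or None
    (with a warning) for an empty ranking.
    """
    rows = ranking.rows[:top] if top else ranking.rows
    if not rows:
        logger.warning("empty ranking for class %s; no plot written",
                       ranking.class_token)
        return None
    out_path = Path(out_path)
    hubs = [r.hub for r in rows]
    zs = [r.z for r in rows]
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.35 * len(rows) + 1)))
    ax.barh(range(len(rows))[::-1], zs, color="#4472a8")
    ax.set_yticks(range(len(rows))[::-1])
    ax.set_yticklabels(hubs)
    ax.set_xlabel("z-score")
    ax.set_title(f"Over-connected {ranking.class_token.replace('_', ' ')}s "
                 f"(p ≤ {ranking.alpha_gate:g})")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    sidecar = out_path.with_suffix(out_path.suffix + ".tsv")
    df = ranking_to_frame(ranking)
    df = df.iloc[:top] if top else df
    df.to_csv(sidecar, sep="\t", index=False)
    return out_path


def screen_inhibitors(rankings: list[ClassRanking], inhibitors: pd.DataFrame,
                      de_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join ranked kinase/protease hubs with the inhibitor table.

    One output row per (hub, compound) pair, ordered by hub z descending
    (then p, then hub, preserving the inhibitor table's compound order
    within a hub). ``direction`` is the hub's own expression call from the DE
    table ('unmeasured' when absent).
    """
    if inhibitors.empty:
        logger.warning("empty inhibitor table; no screening hits")
        return pd.DataFrame(columns=SCREEN_COLUMNS)
    direction_of: dict[str, str] = {}
    if de_table is not None:
        direction_of = dict(zip(de_table["gene_id"], de_table["direction"]))
    pool: list[ConnectivityRecord] = []
    for ranking in rankings:
        if ranking.class_token not in ("kinase", "protease"):
            raise ValueError(
                f"screening applies to kinase/protease rankings, got "
                f"{ranking.class_token!r}"
            )
        pool.extend(ranking.rows)
    pool.sort(key=lambda r: (-r.z, r.p, r.hub))
    rows = []
    for rec in pool:
        hits = inhibitors[inhibitors["target_gene"] == rec.hub]
        for hit in hits.itertuples(index=False):
            rows.append({
                "hub": rec.hub,
                "class": rec.hub_class,
                "z": rec.z,
                "direction": direction_of.get(rec.hub, "unmeasured"),
                "compound": hit.compound,
                "annotation": hit.annotation,
            })
    return pd.DataFrame(rows, columns=SCREEN_COLUMNS)
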
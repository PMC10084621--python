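"""Extreme-score contrast construction and directional DEG intersection.

For each significant canonical axis, two two-group contrasts are formed: the
``n_tail`` individuals with the highest vs the lowest CCp scores, and likewise
for CCe. A gene is a candidate for the axis if it is differentially expressed
at the chosen FDR in BOTH contrasts with the SAME sign of log-fold-change
(positive = higher expression in the high-score group).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import ValidationError


@dataclass
class Contrast:
    axis: int
    basis: str                # "CCp" or "CCe"
    high_ids: list[str]
    low_ids: list[str]

    def __post_init__(self) -> None:
        if set(self.high_ids) & set(self.low_ids):
            raise ValidationError("high and low tails overlap")
        if self.basis not in ("CCp", "CCe"):
            raise ValidationError(f"basis must be CCp or CCe, got {self.basis!r}")


@dataclass
class CandidateGeneSet:
    axis: int
    up: set[str]
    down: set[str]
    conflicting: set[str] = field(default_factory=set)  # significant both, opposite signs
    table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValidationError("a gene cannot be both up and down")


def select_extremes(scores: pd.DataFrame, axis: int, basis: str,
                    n_tail: int = 10) -> Contrast:
    """Pick the ``n_tail`` highest- and lowest-scoring individuals on one axis.

    ``scores`` is the canonical-score table (columns CCp1, CCe1, ...). Ties at
    a tail boundary are broken by ascending individual id, so the selection is
    deterministic across runs.
    """
    col = f"{basis}{axis}"
    if col not in scores.columns:
        raise ValidationError(f"no score column {col!r}")
    if 2 * n_tail > len(scores):
        raise ValidationError(
            f"2*n_tail = {2 * n_tail} exceeds the {len(scores)} scored individuals"
        )
    s = scores[col]
    if not s.notna().all():
        raise ValidationError("scores must be finite")
    order = pd.DataFrame({"score": s.to_numpy(), "id": s.index.astype(str)})
    low = order.sort_values(["score", "id"], ascending=[True, True]).head(n_tail)
    high = order.sort_values(["score", "id"], ascending=[False, True]).head(n_tail)
    return Contrast(axis=axis, basis=basis,
                    high_ids=list(high["id"]), low_ids=list(low["id"]))


def directional_overlap(de_ccp: pd.DataFrame, de_cce: pd.DataFrame,
                        axis: int = 1, fdr: float = 0.05) -> CandidateGeneSet:
    """Intersect two DE tables directionally into the axis candidate set.

    Both tables must cover the same gene universe and carry columns
    ``logFC``, ``fdr`` indexed by gene. Genes significant in both analyses
    with opposite logFC signs are excluded and reported separately.
    """
    if set(de_ccp.index) != set(de_cce.index):
        raise ValidationError("DE tables cover different gene universes")
    cce = de_cce.reindex(de_ccp.index)
    sig = (de_ccp["fdr"] < fdr) & (cce["fdr"] < fdr)
    up_mask = sig & (de_ccp["logFC"] > 0) & (cce["logFC"] > 0)
    down_mask = sig & (de_ccp["logFC"] < 0) & (cce["logFC"] < 0)
    conflict_mask = sig & ~up_mask & ~down_mask
    table = pd.DataFrame({
        "logfc_ccp": de_ccp["logFC"], "logfc_cce": cce["logFC"],
        "fdr_ccp": de_ccp["fdr"], "fdr_cce": cce["fdr"],
        "direction": "",
    })
    table.loc[up_mask, "direction"] = "up"
    table.loc[down_mask, "direction"] = "down"
    table.loc[conflict_mask, "direction"] = "conflict"
    table = table[table["direction"] != ""].sort_index()
    return CandidateGeneSet(
        axis=axis,
        up=set(de_ccp.index[up_mask]),
        down=set(de_ccp.index[down_mask]),
        conflicting=set(de_ccp.index[conflict_mask]),
        table=table,
    )
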
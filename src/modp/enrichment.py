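"""Gene-set scoring by the proportion of true positives.

Each gene set is scored by 1 minus the estimated proportion of true nulls
among its members' p-values, giving a number in [0, 1]: the estimated
fraction of the set that is differentially expressed.  Sets enriched for
signal score above the dataset-wide reference value computed from all
p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GeneSetCollection
from .significance import estimate_pi0

logger = logging.getLogger(__name__)

__all__ = ["SetScoreTable", "set_ptp"]

#: sets with fewer matched genes than this are flagged unreliable
MIN_RELIABLE_SIZE = 5


@dataclass
class SetScoreTable:
    """Per-set proportion-of-true-positive scores and the global reference."""

    table: pd.DataFrame  # set, size, ptp, reliable
    ptp_overall: float

    def to_tsv(self, path, method: str = "modp") -> None:
        out = self.table.copy()
        out["method"] = method
        out.to_csv(path, sep="\t", index=False)


def _ptp(p: np.ndarray, scorer: str) -> float:
    if scorer == "pi0":
        return float(1.0 - estimate_pi0(p))
    if scorer == "mean_lfdr":
        from .significance import local_fdr

        pi0 = estimate_pi0(p)
        return float(np.mean(1.0 - local_fdr(p, pi0)))
    raise ValueError(f"unknown ptp scorer {scorer!r}")


def set_ptp(
    p_values: pd.Series | np.ndarray,
    sets: GeneSetCollection,
    gene_ids=None,
    scorer: str = "pi0",
) -> SetScoreTable:
    """Score every gene set by its estimated proportion of true positives.

    ``p_values`` may be a Series indexed by gene id, or an array accompanied
    by ``gene_ids``.  Sets with no matched genes are dropped (logged); sets
    with fewer than 5 matched members are scored but flagged unreliable
    (their pi0 estimate falls back to the single-lambda rule).
    """
    if isinstance(p_values, pd.Series):
        pv = p_values
    else:
        if gene_ids is None:
            raise ValueError("gene_ids required when p_values is an array")
        pv = pd.Series(np.asarray(p_values, dtype=float), index=list(gene_ids))

    matched = sets.matched(pv.index)
    rows = []
    for name, members in matched.sets.items():
        if not members:
            logger.info("gene set %r has no matched genes: dropped", name)
            continue
        p = pv.loc[members].to_numpy()
        rows.append(
            {
                "set": name,
                "size": len(members),
                "ptp": _ptp(p, scorer),
                "reliable": len(members) >= MIN_RELIABLE_SIZE,
            }
        )
    overall = _ptp(pv.to_numpy(), scorer)
    return SetScoreTable(table=pd.DataFrame(rows), ptp_overall=overall)
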
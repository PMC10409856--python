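"""Gene-set enrichment by Fisher's exact test over an explicit universe.

Each set is tested on the 2x2 table (hit vs non-hit) x (in-set vs out-of-set)
within a caller-supplied gene universe; the universe is never inferred from
the GMT file, since odds ratios depend on it.  BH correction is applied
across sets.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import GeneSets
from .stats import ContingencyTable2x2, bh_fdr, fisher_exact

__all__ = ["enrich"]

log = logging.getLogger(__name__)


def enrich(hits, universe, sets: GeneSets) -> pd.DataFrame:
    """Fisher's exact enrichment of ``hits`` within ``universe`` for each set.

    Hits must be a subset of the universe; set members are intersected with
    the universe before testing, and sets that become empty are skipped with a
    log entry.  Returns a DataFrame per set: a, b, c, d (table cells), the
    sample odds ratio, two-sided p, and BH q across sets.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    rows = []
    for name, members in sets:
        inset = members & universe
        if not inset:
            log.info("enrich: set %r empty after universe intersection; skipped", name)
            continue
        a = len(hits & inset)                    # hit, in set
        b = len(hits - inset)                    # hit, out of set
        c = len(inset - hits)                    # non-hit, in set
        d = len(universe - hits - inset)         # non-hit, out of set
        odds, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        rows.append((name, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p"]
                       ).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out
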
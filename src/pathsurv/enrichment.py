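"""Gene-set overrepresentation analysis (ORA) with FDR control.

Standard hypergeometric ORA of a selected gene list against a GMT
collection, restricted to the analyzable universe (the protein-coding,
expressed features that survived filtering — not the whole genome),
with Benjamini-Hochberg adjustment and per-pathway up/down composition.
This is the open stand-in for proprietary canonical-pathway enrichment
tools: the test is the textbook one-sided hypergeometric, the universe
and memberships are whatever collection the caller supplies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError
from .genesets import GeneSetCollection

log = logging.getLogger(__name__)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Values must lie in (0, 1]; the adjustment is monotone-enforced and
    capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    selected,
    universe,
    sets: GeneSetCollection,
    up=None,
    down=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation per gene set.

    Parameters
    ----------
    selected
        DE gene ids; must be a subset of *universe*.
    universe
        All analyzable gene ids (the tested feature space).
    sets
        Gene-set collection; members are intersected with the universe
        before testing and sets falling entirely outside it are skipped
        with a warning.
    up, down
        Optional disjoint partitions of *selected* used to annotate the
        per-set composition (n_up / n_down).

    Returns rows sorted by adjusted p-value with columns: set_name, k
    (overlap), K (set size in universe), n (selected), N (universe),
    p_hyper = P(X >= k), p_bh, significant (p_bh < alpha), and n_up /
    n_down when a partition is given.
    """
    uni = set(universe)
    sel = set(selected)
    offenders = sorted(sel - uni)
    if offenders:
        raise ValidationError(
            f"selected genes outside the universe: {offenders[:10]}"
            + ("..." if len(offenders) > 10 else "")
        )
    restricted = sets.restrict_to(uni)
    n, big_n = len(sel), len(uni)
    rows = []
    for name in restricted.names:
        members = set(restricted[name])
        big_k = len(members)
        k = len(members & sel)
        p = float(hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"set_name": name, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p_hyper": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_hyper"])
    if len(out):
        out["p_bh"] = bh_adjust(out["p_hyper"])
        out["significant"] = out["p_bh"] < alpha
    else:
        out["p_bh"] = []
        out["significant"] = []
    if up is not None or down is not None:
        comp = direction_composition(restricted, up or [], down or [])
        out = out.merge(comp, on="set_name", how="left")
    out = out.sort_values(["p_bh", "p_hyper", "set_name"]).reset_index(drop=True)
    return out


def direction_composition(
    sets: GeneSetCollection, up, down
) -> pd.DataFrame:
    """Count each set's members on the up- and down-regulated lists.

    Fractions are relative to the set's (universe-restricted) size.
    """
    up_set, down_set = set(up), set(down)
    overlap = up_set & down_set
    if overlap:
        raise ValidationError(
            f"up and down lists overlap: {sorted(overlap)[:10]}"
        )
    rows = []
    for name in sets.names:
        members = set(sets[name])
        n_up = len(members & up_set)
        n_down = len(members & down_set)
        size = len(members)
        rows.append(
            {
                "set_name": name,
                "n_up": n_up,
                "n_down": n_down,
                "frac_up": n_up / size,
                "frac_down": n_down / size,
            }
        )
    return pd.DataFrame(
        rows, columns=["set_name", "n_up", "n_down", "frac_up", "frac_down"]
    )
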
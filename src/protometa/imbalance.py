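"""Enzyme-centred metabolic imbalance scoring.

For every enzyme and each of its reactions, metabolites are collected
upstream (following reactant edges backwards through producing reactions)
and downstream (following product edges forwards through consuming
reactions) by breadth-first traversal, recording the minimal reaction-step
distance d of each metabolite up to a maximum depth.  A metabolite at
distance d carries weight p^-(d-1), so direct reactants/products count
fully and influence decays geometrically with the distance penalty p
(default 8).

Feeding per-metabolite differential t-values into these signatures gives a
weighted-mean differential score per side; the imbalance of a reaction is
downstream minus upstream, negated for reactions annotated as reverse, and
enzymes participating in several reactions average their reaction scores.
A strongly positive imbalance marks a bottleneck: metabolites accumulate
below the enzyme while its substrates are depleted above it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ImbalanceParams
from .network import ReactionNetwork


@dataclass
class SignatureWeights:
    """Distance-decayed metabolite weights per (enzyme, reaction) and side."""

    weights: dict  # (enzyme, reaction) -> {"upstream": {met: w}, "downstream": {met: w}}
    params: ImbalanceParams = field(default_factory=ImbalanceParams)


def _traverse(
    net: ReactionNetwork, enzyme: str, reaction: str, direction: str, max_depth: int
) -> dict[str, int]:
    """Minimal reaction-step distance per metabolite on one side of a reaction."""
    g = net.graph
    if direction == "upstream":
        frontier = set(net.reactants(enzyme, reaction))
    else:
        frontier = set(net.products(enzyme, reaction))
    dist = {m: 1 for m in frontier}
    depth = 1
    while frontier and depth < max_depth:
        depth += 1
        nxt = set()
        for met in frontier:
            if direction == "upstream":
                # producers of met, then their reactants one step further up
                hops = [
                    (e, a["reaction"])
                    for e, _, a in g.in_edges(met, data=True)
                ]
                expand = lambda e, r: net.reactants(e, r)
            else:
                hops = [
                    (e, a["reaction"])
                    for _, e, a in g.out_edges(met, data=True)
                ]
                expand = lambda e, r: net.products(e, r)
            for e, r in hops:
                for m2 in expand(e, r):
                    if m2 not in dist:
                        dist[m2] = depth
                        nxt.add(m2)
        frontier = nxt
    return dist


def build_signatures(
    net: ReactionNetwork, cfg: ImbalanceParams | None = None
) -> SignatureWeights:
    """Upstream/downstream metabolite weights for every (enzyme, reaction)."""
    cfg = cfg or ImbalanceParams()
    cfg.validate()
    weights: dict = {}
    for enzyme in net.enzymes:
        for reaction in net.reactions_of(enzyme):
            sides = {}
            for direction in ("upstream", "downstream"):
                dist = _traverse(net, enzyme, reaction, direction, cfg.max_depth)
                sides[direction] = {
                    m: cfg.distance_penalty ** -(d - 1) for m, d in dist.items()
                }
            weights[(enzyme, reaction)] = sides
    return SignatureWeights(weights=weights, params=cfg)


@dataclass
class ImbalanceResult:
    """Per-enzyme averaged side scores and imbalance."""

    table: pd.DataFrame  # index enzyme: upstream, downstream, imbalance, n_reactions

    @property
    def imbalance(self) -> pd.Series:
        return self.table["imbalance"]


def _side_score(side: dict[str, float], metab_t: dict[str, float]) -> float | None:
    num = den = 0.0
    for met, w in side.items():
        t = metab_t.get(met)
        if t is not None and np.isfinite(t):
            num += w * t
            den += w
    return num / den if den > 0 else None


def score_imbalance(
    sig: SignatureWeights, metab_t: dict[str, float], net: ReactionNetwork
) -> ImbalanceResult:
    """Weighted-mean side scores and downstream-minus-upstream imbalance.

    Reactions lacking a measured metabolite on either side are skipped;
    reverse-flagged reactions have their imbalance negated; per-enzyme
    results average over its scored reactions.  Enzymes with no scored
    reaction are reported as missing.
    """
    measured = {
        m: t for m, t in metab_t.items() if t is not None and np.isfinite(t)
    }
    if not measured:
        raise ValueError("no measured metabolite t-values")
    per_enzyme: dict[str, list[tuple[float, float, float]]] = {}
    for (enzyme, reaction), sides in sig.weights.items():
        up = _side_score(sides["upstream"], measured)
        down = _side_score(sides["downstream"], measured)
        if up is None or down is None:
            continue
        imb = down - up
        if net.reverse.get(reaction, False):
            imb = -imb
        per_enzyme.setdefault(enzyme, []).append((up, down, imb))
    rows = {}
    for enzyme in net.enzymes:
        scored = per_enzyme.get(enzyme, [])
        if scored:
            arr = np.array(scored)
            rows[enzyme] = {
                "upstream": arr[:, 0].mean(),
                "downstream": arr[:, 1].mean(),
                "imbalance": arr[:, 2].mean(),
                "n_reactions": len(scored),
            }
        else:
            rows[enzyme] = {
                "upstream": np.nan,
                "downstream": np.nan,
                "imbalance": np.nan,
                "n_reactions": 0,
            }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "enzyme"
    return ImbalanceResult(table=table)


def correlate_with_proteomics(
    imb: ImbalanceResult,
    prot_t: dict[str, float] | pd.Series,
    enzyme_subset: set | None = None,
) -> tuple[float, float]:
    """Pearson correlation of per-enzyme imbalance with proteomic t-values.

    ``enzyme_subset`` optionally restricts the comparison to a curated
    pathway (e.g. the canonical TCA-cycle enzymes).
    """
    prot = pd.Series(prot_t, dtype=float)
    imbal = imb.imbalance.dropna()
    shared = imbal.index.intersection(prot.dropna().index)
    if enzyme_subset is not None:
        shared = shared.intersection(sorted(enzyme_subset))
    if len(shared) < 3:
        raise ValueError("need >= 3 enzymes with both imbalance and proteomic t")
    r = stats.pearsonr(imbal.loc[shared], prot.loc[shared])
    return float(r.statistic), float(r.pvalue)


def write_imbalance(result: ImbalanceResult, path) -> None:
    result.table.to_csv(path, sep="\t", na_rep="NA")
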
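"""Mixed gene+metabolite pathway enrichment with a permutation null.

Pathway collections (e.g. the MSigDB cancer hallmarks) annotate genes, not
metabolites.  To score both molecular layers jointly, each measured
metabolite inherits the pathway memberships of every enzyme it is adjacent
to in the reaction network (as reactant or product), giving a mixed
ontology over genes and metabolites.

Per-patient log2 fold changes are z-scored across patients and summarised
per pathway by the weighted-mean statistic (membership weights 1, i.e. the
sum of member z-scores).  The raw score is standardised against an
empirical null obtained by permuting the value vector over all measured
features B times and recomputing the score on the same membership
positions; the normalized score is the number of null standard deviations
the observed score sits away from the null mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import ReactionNetwork


class GmtFormatError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named sets of typed members: member id -> 'gene' | 'metabolite'."""

    sets: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise GmtFormatError(f"set {name!r} is empty")

    def members(self, name: str, kind: str | None = None) -> list:
        m = self.sets[name]
        if kind is None:
            return list(m)
        return [i for i, t in m.items() if t == kind]

    def restrict(self, kind: str) -> "GeneSetCollection":
        """Sub-collection keeping only members of one type (drops empty sets)."""
        sub = {
            name: {i: t for i, t in members.items() if t == kind}
            for name, members in self.sets.items()
        }
        return GeneSetCollection({n: m for n, m in sub.items() if m})

    @property
    def names(self) -> list:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: per line, set name, description, tab-separated members."""
    sets: dict[str, dict[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}: line {lineno} has no members (name and description only)"
                )
            name = fields[0]
            if name in sets:
                raise GmtFormatError(f"{path}: duplicate set name {name!r}")
            members = [f for f in fields[2:] if f]
            if not members:
                raise GmtFormatError(f"{path}: line {lineno} has no members")
            sets[name] = {m: "gene" for m in members}
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names:
            fh.write("\t".join([name, description, *collection.members(name)]) + "\n")


def transfer_hallmarks(
    sets: GeneSetCollection, net: ReactionNetwork
) -> GeneSetCollection:
    """Extend gene sets with metabolites adjacent to their member enzymes.

    Every metabolite that is a reactant or product of an enzyme belonging to
    pathway H is added to H with type 'metabolite'; gene members are never
    removed.  If no network enzyme appears in any set, the collection is
    returned unchanged with a warning.
    """
    enzymes = set(net.enzymes)
    all_members = set().union(*(set(m) for m in sets.sets.values()))
    if not enzymes & all_members:
        warnings.warn(
            "no network enzyme matches any set member; sets returned unchanged",
            stacklevel=2,
        )
        return GeneSetCollection({n: dict(m) for n, m in sets.sets.items()})
    out: dict[str, dict[str, str]] = {}
    for name, members in sets.sets.items():
        new = dict(members)
        for member in members:
            if member in enzymes:
                for met in net.adjacent_metabolites(member):
                    new.setdefault(met, "metabolite")
        out[name] = new
    return GeneSetCollection(out)


# ---------------------------------------------------------------------------
# per-patient fold changes


def patient_log2fc(
    m, ann, value_cond: str = "TT", ref_cond: str = "NAT"
) -> pd.DataFrame:
    """Per-patient log2 fold change (value_cond - ref_cond) from a log2 matrix.

    Expects one sample per subject and condition in the annotation subset;
    returns a feature x subject DataFrame.
    """
    if not m.is_log:
        raise ValueError("patient_log2fc expects a log-scale matrix")
    ann = ann.for_samples(m.sample_ids)
    t = ann.table
    cols = {}
    for subject, grp in t.groupby("subject_id"):
        tt = grp.loc[grp["condition"] == value_cond, "sample_id"]
        nat = grp.loc[grp["condition"] == ref_cond, "sample_id"]
        if len(tt) != 1 or len(nat) != 1:
            raise ValueError(
                f"subject {subject!r}: need exactly one {value_cond} and one "
                f"{ref_cond} sample, got {len(tt)}/{len(nat)}"
            )
        cols[subject] = m.values[tt.iloc[0]] - m.values[nat.iloc[0]]
    return pd.DataFrame(cols)


def zscore_across_patients(fc: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-score across patient columns (sample SD, n-1).

    Features observed in fewer than 2 patients or with zero variance become
    all-missing rows.
    """
    if fc.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 patients")
    vals = fc.to_numpy(dtype=float)
    n_obs = np.isfinite(vals).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    bad = (n_obs < 2) | (sd[:, 0] == 0) | ~np.isfinite(sd[:, 0])
    z[bad] = np.nan
    return pd.DataFrame(z, index=fc.index, columns=fc.columns)


# ---------------------------------------------------------------------------
# weighted-mean enrichment


@dataclass
class EnrichmentResult:
    """Set x patient enrichment scores with their permutation null."""

    raw: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    normalized: pd.DataFrame
    B: int
    seed: int
    skipped: list = field(default_factory=list)  # sets with < 2 measured members
    degenerate: list = field(default_factory=list)  # sets with zero null SD


def wmean_enrichment(
    values: pd.DataFrame | pd.Series,
    sets: GeneSetCollection,
    B: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted-mean set scores normalized against a permutation null.

    ``values`` is a feature x patient DataFrame (a Series is treated as one
    column) of z-scores; missing features are dropped per the measured
    universe.  The raw score of a set is the sum of its measured members'
    values (membership weight 1).  The null redraws the value vector by
    permutation over all measured features, identically across patients, so
    scores are comparable between columns.  Features are put in canonical
    (sorted-id) order before permuting, making the null invariant to input
    row order.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if isinstance(values, pd.Series):
        values = values.to_frame("score")
    measured = values.dropna(how="all")
    measured = measured.loc[sorted(measured.index.astype(str))]
    X = np.nan_to_num(measured.to_numpy(dtype=float), nan=0.0)
    feat_pos = {f: i for i, f in enumerate(measured.index)}
    names, rows, skipped = [], [], []
    for name in sets.names:
        pos = [feat_pos[m] for m in sets.members(name) if m in feat_pos]
        if len(pos) < 2:
            skipped.append(name)
            continue
        names.append(name)
        rows.append(pos)
    S = np.zeros((len(names), X.shape[0]))
    for i, pos in enumerate(rows):
        S[i, pos] = 1.0
    raw = S @ X

    rng = np.random.default_rng(seed)
    null = np.empty((B, *raw.shape))
    for b in range(B):
        null[b] = S @ X[rng.permutation(X.shape[0])]
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    # a permutation-invariant score (e.g. set = universe) has zero null
    # spread up to float summation order; treat that as degenerate
    degenerate_mask = null_sd <= 1e-9 * np.maximum(1.0, np.abs(null_mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = (raw - null_mean) / null_sd
    degenerate = [names[i] for i in np.where(degenerate_mask.any(axis=1))[0]]
    normalized[degenerate_mask] = np.nan

    cols = list(values.columns)
    as_df = lambda a: pd.DataFrame(a, index=names, columns=cols)
    return EnrichmentResult(
        raw=as_df(raw),
        null_mean=as_df(null_mean),
        null_sd=as_df(null_sd),
        normalized=as_df(normalized),
        B=B,
        seed=seed,
        skipped=skipped,
        degenerate=degenerate,
    )


def run_configurations(
    prot_fc: pd.DataFrame,
    metab_fc: pd.DataFrame | None,
    sets: GeneSetCollection,
    mixed_sets: GeneSetCollection | None,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Enrichment in the three data configurations.

    'proteins': gene features against gene members only; 'integrated':
    concatenated gene+metabolite features against the mixed ontology;
    'averaged': element-wise mean of the separate gene and metabolite
    normalized scores (sets measured in only one modality keep that score).
    Returns a dict of the two EnrichmentResults plus the averaged DataFrame.
    """
    gene_sets = sets.restrict("gene")
    res_prot = wmean_enrichment(prot_fc, gene_sets, B=B, seed=seed)
    if metab_fc is None or metab_fc.empty:
        return {
            "proteins": res_prot,
            "integrated": res_prot,
            "averaged": res_prot.normalized.copy(),
        }
    if mixed_sets is None:
        raise ValueError("mixed ontology required when metabolite data is provided")
    combined = pd.concat([prot_fc, metab_fc], axis=0)
    res_int = wmean_enrichment(combined, mixed_sets, B=B, seed=seed)
    res_met = wmean_enrichment(metab_fc, mixed_sets.restrict("metabolite"), B=B, seed=seed)
    averaged = pd.concat(
        [res_prot.normalized, res_met.normalized], keys=["gene", "metabolite"]
    ).groupby(level=1).mean()
    return {"proteins": res_prot, "integrated": res_int, "averaged": averaged}


# ---------------------------------------------------------------------------
# cross-method comparison


def _normalized_frame(e) -> pd.DataFrame:
    return e.normalized if isinstance(e, EnrichmentResult) else e


def compare_methods(e1, e2) -> dict:
    """Pearson correlation of enrichment scores between two methods.

    Correlates over shared sets, per patient column and pooled; rows with a
    missing score in either matrix are dropped pairwise.
    """
    m1, m2 = _normalized_frame(e1), _normalized_frame(e2)
    shared_sets = m1.index.intersection(m2.index)
    shared_pat = m1.columns.intersection(m2.columns)
    if len(shared_sets) < 3:
        raise ValueError("need >= 3 shared sets")
    per_patient = {}
    for pat in shared_pat:
        x = m1.loc[shared_sets, pat]
        y = m2.loc[shared_sets, pat]
        keep = x.notna() & y.notna()
        per_patient[pat] = float(stats.pearsonr(x[keep], y[keep]).statistic)
    x = m1.loc[shared_sets, shared_pat].to_numpy().ravel()
    y = m2.loc[shared_sets, shared_pat].to_numpy().ravel()
    keep = np.isfinite(x) & np.isfinite(y)
    pooled = float(stats.pearsonr(x[keep], y[keep]).statistic)
    return {"per_patient": per_patient, "pooled": pooled}


def test_correlation_difference(r1, r2) -> tuple[float, int, float]:
    """Paired Student t-test on per-patient correlation coefficients.

    Returns (t, df, p) with df = n - 1.  When the paired differences are
    identically zero the test is degenerate and reported as t = 0, p = 1.
    """
    d = np.asarray(r1, dtype=float) - np.asarray(r2, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need >= 2 paired correlation coefficients")
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p
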
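"""Synthetic paired tumour/normal cohorts, sequences and toy networks.

The cohort generator emulates the structure of a paired-design clinical
proteo-metabolomics study: ten subjects, each contributing tumour (TT) and
matched adjacent normal (NAT) tissue, measured under two sample-preparation
methods that share one underlying biology (the planted TT-vs-NAT effects)
but differ by small per-feature method offsets.  Log2 intensities follow

    x = baseline_f + b_{f,subject} + effect_f * 1[TT] + offset_{f,method} + eps,

with subject random effects sized so repeated measures of a subject have
within-subject correlation rho_block, and with abundance-dependent
missingness (lower-abundance measurements drop out more often; slope 0
recovers missing-completely-at-random).  Every generator is a pure
function of its parameters including the seed, and each simulation returns
a ground-truth record so downstream estimates can be checked against what
was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import FeatureMatrix, QualityMatrix, SampleAnnotation
from .network import ReactionNetwork, from_edges
from .physchem import AMINO_ACIDS, SequenceRecord


@dataclass
class SimulationParams:
    n_subjects: int = 10
    conditions: tuple[str, str] = ("NAT", "TT")
    methods: tuple[str, str] = ("autoSP3", "MTBE-SP3")
    n_proteins: int = 2000
    n_metabolites: int = 300
    fraction_de: float = 0.1
    effect_size_mean: float = 1.0  # log2 units
    effect_size_sd: float = 0.25
    patient_effect_sd: float = 1.0  # per-patient tumour-effect heterogeneity, log2
    pathway_activity_sd: float = 0.5  # per-patient coherent hallmark activity, log2
    method_offset_sd: float = 0.1  # log2 units
    rho_block: float = 0.3  # within-subject correlation of repeated measures
    noise_sd: float = 0.25  # log2 units
    missing_rate_base: float = 0.05
    missing_abundance_slope: float = 0.5  # logit units per log2 below the median
    n_hallmark_sets: int = 50
    hallmark_set_size: int = 30
    matrix_type: str = "fresh-frozen"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_de", "missing_rate_base"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.rho_block < 1:
            raise ValueError("rho_block must be in [0, 1)")
        for name in ("n_subjects", "n_proteins", "n_metabolites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CohortTruth:
    """What was planted: per-feature effects, DE flags, set memberships."""

    effects: pd.Series  # true log2 TT - NAT effect per feature
    is_de: pd.Series  # boolean, |effect| > 0
    hallmark_sets: dict = field(default_factory=dict)  # set name -> member ids
    active_set: str | None = None  # set whose members carry planted effects
    bottleneck_enzyme: str | None = None

    def to_json(self, path) -> None:
        payload = {
            "effects": self.effects.to_dict(),
            "is_de": {k: bool(v) for k, v in self.is_de.items()},
            "hallmark_sets": {k: sorted(v) for k, v in self.hallmark_sets.items()},
            "active_set": self.active_set,
            "bottleneck_enzyme": self.bottleneck_enzyme,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _subject_sd(p: SimulationParams) -> float:
    # rho = sb^2 / (sb^2 + se^2)  =>  sb^2 = rho/(1-rho) * se^2
    return p.noise_sd * np.sqrt(p.rho_block / (1.0 - p.rho_block))


def _plant_effects(
    rng: np.random.Generator, ids: list[str], p: SimulationParams
) -> pd.Series:
    effects = pd.Series(0.0, index=ids)
    n_de = int(round(p.fraction_de * len(ids)))
    if n_de:
        chosen = rng.choice(len(ids), size=n_de, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_de)
        sizes = rng.normal(p.effect_size_mean, p.effect_size_sd, size=n_de)
        effects.iloc[chosen] = signs * np.abs(sizes)
    return effects


def _simulate_block(
    rng: np.random.Generator,
    ids: list[str],
    sample_meta: pd.DataFrame,
    baselines: np.ndarray,
    effects: pd.Series,
    offsets: dict[str, np.ndarray],
    patient_effects: dict[str, np.ndarray],
    p: SimulationParams,
) -> pd.DataFrame:
    """Log2 intensities for one feature panel over the given samples.

    ``patient_effects`` holds per-subject tumour-effect deviations shared by
    every method measuring that subject — the patient-level biology both
    sample-preparation routes see in common.
    """
    n_feat, n_samp = len(ids), len(sample_meta)
    subj_sd = _subject_sd(p)
    subjects = sorted(sample_meta["subject_id"].unique())
    b = {s: rng.normal(0.0, subj_sd, size=n_feat) for s in subjects}
    x = np.empty((n_feat, n_samp))
    for j, row in enumerate(sample_meta.itertuples(index=False)):
        is_tumour = row.condition == p.conditions[1]
        x[:, j] = (
            baselines
            + b[row.subject_id]
            + (effects.to_numpy() + patient_effects[row.subject_id]) * is_tumour
            + offsets[row.method]
            + rng.normal(0.0, p.noise_sd, size=n_feat)
        )
    return pd.DataFrame(x, index=ids, columns=list(sample_meta["sample_id"]))


def _apply_missingness(
    rng: np.random.Generator, x: pd.DataFrame, p: SimulationParams
) -> pd.DataFrame:
    if p.missing_rate_base == 0:
        return x
    vals = x.to_numpy()
    base_logit = np.log(p.missing_rate_base / (1.0 - p.missing_rate_base))
    centered = vals - np.nanmedian(vals)
    logit = base_logit - p.missing_abundance_slope * centered
    prob = 1.0 / (1.0 + np.exp(-logit))
    mask = rng.random(vals.shape) < prob
    out = vals.copy()
    out[mask] = np.nan
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def simulate_cohort(
    p: SimulationParams,
) -> tuple[FeatureMatrix, FeatureMatrix, QualityMatrix, SampleAnnotation, CohortTruth]:
    """Paired TT/NAT cohort under two extraction methods plus a metabolite panel.

    Proteins are measured per subject x condition x method (raw, unlogged
    LFQ-style intensities); metabolites once per subject x condition
    (concentrations, via the biphasic extraction route only) with a parallel
    quality-status matrix marking sub-detection-limit cells.  One hallmark
    set ('H1') is planted as active: all its members receive a positive
    TT-vs-NAT effect.
    """
    rng = np.random.default_rng(p.seed)
    prot_ids = [f"P{i:04d}" for i in range(p.n_proteins)]
    met_ids = [f"m{i:04d}" for i in range(p.n_metabolites)]

    effects = pd.concat(
        [_plant_effects(rng, prot_ids, p), _plant_effects(rng, met_ids, p)]
    )

    # planted hallmark sets over proteins; the first one is enriched for
    # positive effects so pathway-level recovery is testable
    hallmark_sets: dict[str, set] = {}
    active = None
    if p.n_hallmark_sets > 0 and p.hallmark_set_size <= p.n_proteins:
        for s in range(p.n_hallmark_sets):
            members = rng.choice(prot_ids, size=p.hallmark_set_size, replace=False)
            hallmark_sets[f"H{s + 1}"] = set(members)
        active = "H1"
        for m in hallmark_sets[active]:
            effects[m] = abs(
                rng.normal(p.effect_size_mean, p.effect_size_sd)
            ) if p.fraction_de > 0 else 0.0

    subjects = [f"S{i + 1:02d}" for i in range(p.n_subjects)]
    prot_rows = [
        {
            "sample_id": f"{s}_{c}_{m}",
            "subject_id": s,
            "condition": c,
            "method": m,
            "matrix_type": p.matrix_type,
        }
        for s in subjects
        for c in p.conditions
        for m in p.methods
    ]
    met_rows = [
        {
            "sample_id": f"{s}_{c}_met",
            "subject_id": s,
            "condition": c,
            "method": p.methods[1],
            "matrix_type": p.matrix_type,
        }
        for s in subjects
        for c in p.conditions
    ]
    ann = SampleAnnotation(pd.DataFrame(prot_rows + met_rows))

    prot_base = rng.normal(25.0, 2.0, size=p.n_proteins)
    prot_off = {m: rng.normal(0.0, p.method_offset_sd, size=p.n_proteins) for m in p.methods}
    prot_gamma = {
        s: rng.normal(0.0, p.patient_effect_sd, size=p.n_proteins) for s in subjects
    }
    # coherent per-patient pathway activity: members of a hallmark move
    # together within a patient's tumour, identically under both methods
    if hallmark_sets and p.pathway_activity_sd > 0:
        prot_pos = {f: i for i, f in enumerate(prot_ids)}
        for members in hallmark_sets.values():
            idx = [prot_pos[f] for f in members]
            for s in subjects:
                prot_gamma[s][idx] += rng.normal(0.0, p.pathway_activity_sd)
    prot_log2 = _simulate_block(
        rng, prot_ids, pd.DataFrame(prot_rows), prot_base,
        effects.loc[prot_ids], prot_off, prot_gamma, p,
    )
    prot_log2 = _apply_missingness(rng, prot_log2, p)
    proteins = FeatureMatrix(
        values=np.power(2.0, prot_log2), is_log=False, feature_kind="protein"
    )

    met_base = rng.normal(5.0, 1.5, size=p.n_metabolites)
    met_off = {m: np.zeros(p.n_metabolites) for m in p.methods}
    met_gamma = {
        s: rng.normal(0.0, p.patient_effect_sd, size=p.n_metabolites) for s in subjects
    }
    met_log2 = _simulate_block(
        rng, met_ids, pd.DataFrame(met_rows), met_base,
        effects.loc[met_ids], met_off, met_gamma, p,
    )
    met_log2 = _apply_missingness(rng, met_log2, p)
    met_conc = np.power(2.0, met_log2)
    # detection limit at the 5th percentile of simulated concentrations
    detect_limit = np.nanquantile(met_conc.to_numpy(), 0.05)
    statuses = np.where(
        met_conc.isna(), "missing", np.where(met_conc < detect_limit, "below_limit", "valid")
    )
    metabolites = FeatureMatrix(values=met_conc, is_log=False, feature_kind="metabolite")
    quality = QualityMatrix(
        statuses=pd.DataFrame(statuses, index=met_conc.index, columns=met_conc.columns)
    )

    truth = CohortTruth(
        effects=effects,
        is_de=effects.abs() > 0,
        hallmark_sets=hallmark_sets,
        active_set=active,
    )
    return proteins, metabolites, quality, ann, truth


def simulate_replicate_sets(
    n_rep: int,
    n_features: int = 500,
    methods: tuple[str, str] = ("autoSP3", "MTBE-SP3"),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[FeatureMatrix, SampleAnnotation]:
    """Technical replicates of one pooled sample under two methods.

    Both method groups scatter around shared per-feature means, so any
    between-method differential signal is a false positive; used for CV and
    replicate-correlation checks.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(n_features)]
    base = rng.normal(25.0, 2.0, size=n_features)
    cols, rows = {}, []
    for method in methods:
        for r in range(n_rep):
            sid = f"{method}_rep{r + 1}"
            cols[sid] = base + rng.normal(0.0, noise_sd, size=n_features)
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": "pool",
                    "condition": "replicate",
                    "method": method,
                    "matrix_type": "cells",
                }
            )
    values = np.power(2.0, pd.DataFrame(cols, index=ids))
    return (
        FeatureMatrix(values=values, is_log=False, feature_kind="protein"),
        SampleAnnotation(pd.DataFrame(rows)),
    )


_HYDROPHOBIC = set("AILMFVWC")
_BASIC = set("KRH")


def simulate_sequences(
    n: int,
    length_range: tuple[int, int] = (7, 30),
    bias: str | None = None,
    bias_strength: float = 3.0,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Random peptide sequences over the 20 standard amino acids.

    ``bias`` = 'hydrophobic' or 'basic' up-weights the corresponding residue
    class by ``bias_strength``, for constructing association-test fixtures.
    """
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    weights = np.ones(len(AMINO_ACIDS))
    if bias == "hydrophobic":
        boost = _HYDROPHOBIC
    elif bias == "basic":
        boost = _BASIC
    elif bias is None:
        boost = set()
    else:
        raise ValueError(f"unknown bias {bias!r}")
    for i, aa in enumerate(AMINO_ACIDS):
        if aa in boost:
            weights[i] *= bias_strength
    weights /= weights.sum()
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        letters = rng.choice(list(AMINO_ACIDS), size=length, p=weights)
        records.append(SequenceRecord(id=f"pep{i:04d}", sequence="".join(letters)))
    return records


def simulate_network_truth(
    n_linear: int,
    bottleneck_index: int,
    magnitude: float = 2.0,
    jitter: float = 0.2,
    seed: int = 0,
) -> tuple[ReactionNetwork, dict[str, float], CohortTruth]:
    """Linear reaction chain with one planted bottleneck enzyme.

    The chain M1 -> E1 -> M2 -> ... -> Mn mimics a TCA-like pathway; the
    enzyme at ``bottleneck_index`` (0-based among E1..E_{n-1}) is the
    bottleneck: every metabolite upstream of it carries a negative
    differential t-value and every metabolite downstream a positive one,
    with magnitudes jittered multiplicatively by +/- ``jitter``.
    """
    if n_linear < 3:
        raise ValueError("need a chain of at least 3 metabolites")
    n_enzymes = n_linear - 1
    if not 0 <= bottleneck_index < n_enzymes:
        raise ValueError(
            f"bottleneck_index {bottleneck_index} out of range [0, {n_enzymes})"
        )
    rng = np.random.default_rng(seed)
    mets = [f"M{i + 1}" for i in range(n_linear)]
    enzymes = [f"E{i + 1}" for i in range(n_enzymes)]
    edges, kinds = [], {}
    for m in mets:
        kinds[m] = "metabolite"
    for e in enzymes:
        kinds[e] = "enzyme"
    for i, e in enumerate(enzymes):
        rid = f"R{i + 1}"
        edges.append((mets[i], e, rid))
        edges.append((e, mets[i + 1], rid))
    net = from_edges(edges, kinds, reverse={f"R{i + 1}": False for i in range(n_enzymes)})

    t_values = {}
    for i, m in enumerate(mets):
        sign = -1.0 if i <= bottleneck_index else 1.0
        scale = 1.0 + rng.uniform(-jitter, jitter)
        t_values[m] = sign * magnitude * scale
    effects = pd.Series(t_values)
    truth = CohortTruth(
        effects=effects,
        is_de=effects.abs() > 0,
        bottleneck_enzyme=enzymes[bottleneck_index],
    )
    return net, t_values, truth


def params_manifest(p: SimulationParams) -> dict:
    return asdict(p)
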
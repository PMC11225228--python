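"""Sequence physico-chemical properties: GRAVY and isoelectric point.

Differences in protein extraction chemistry can bias which proteins a
workflow recovers.  Two summary properties capture most of that bias:
the grand average of hydropathy (GRAVY; Kyte-Doolittle residue hydropathy
averaged over the sequence — positive means hydrophobic) and the
isoelectric point (pI; the pH at which the net charge of the molecule is
zero).  Correlating either property with differential-abundance t-values
between two sample-preparation methods is a direct diagnostic of
extraction bias: a non-zero Spearman rho means one method preferentially
recovers, say, hydrophobic or basic species.

The net charge at a given pH follows the Henderson-Hasselbalch census over
the nine ionizable groups (one N-terminus, one C-terminus, and every D, E,
C, Y, H, K, R side chain), with the IPC_protein pKa constants packaged as a
data file.  Charge is strictly decreasing in pH, so the pI is the unique
root on [0, 14], found by bisection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InvalidSequenceError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        for ch in self.sequence:
            if ch not in AMINO_ACIDS:
                raise InvalidSequenceError(
                    f"{self.id}: invalid residue {ch!r} (only the 20 standard "
                    "one-letter codes are accepted)"
                )


@dataclass(frozen=True)
class PhyschemResult:
    id: str
    length: int
    gravy: float
    isoelectric_point: float


def _load_table(name: str) -> list[dict]:
    text = (resources.files("protometa") / "constants" / name).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


def load_hydropathy_table() -> dict[str, float]:
    """Kyte-Doolittle residue hydropathy values (20 entries)."""
    table = {row["residue"]: float(row["hydropathy"]) for row in _load_table("kyte_doolittle.tsv")}
    assert len(table) == 20
    return table


def load_pka_table() -> dict[str, tuple[float, str]]:
    """IPC_protein pKa set: group -> (pKa, 'acidic'|'basic'), 9 entries."""
    table = {row["group"]: (float(row["pka"]), row["kind"]) for row in _load_table("ipc_pka.tsv")}
    assert len(table) == 9
    return table


_HYDROPATHY = load_hydropathy_table()
_PKA = load_pka_table()


def gravy(record: SequenceRecord, table: dict[str, float] | None = None) -> float:
    """Grand average of hydropathy: mean residue hydropathy over the sequence."""
    tab = _HYDROPATHY if table is None else table
    return sum(tab[ch] for ch in record.sequence) / len(record.sequence)


def net_charge(
    record: SequenceRecord, pH: float, pka: dict[str, tuple[float, str]] | None = None
) -> float:
    """Net charge at ``pH`` from the Henderson-Hasselbalch group census.

    Basic groups contribute +1/(1 + 10^(pH - pKa)); acidic groups contribute
    -1/(1 + 10^(pKa - pH)).  One N-terminal and one C-terminal group are
    always counted, plus every matching side chain.
    """
    tab = _PKA if pka is None else pka
    groups = ["nterm", "cterm"] + [ch for ch in record.sequence if ch in tab]
    charge = 0.0
    for g in groups:
        pk, kind = tab[g]
        if kind == "basic":
            charge += 1.0 / (1.0 + 10.0 ** (pH - pk))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pk - pH))
    return charge


def isoelectric_point(
    record: SequenceRecord,
    pka: dict[str, tuple[float, str]] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The charge function is strictly decreasing in pH (every Henderson-
    Hasselbalch term is), positive at pH 0 and negative at pH 14, so the
    root exists and is unique; bisection terminates when the bracket is
    narrower than ``tol`` pH units.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(record, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem_profile(records: list[SequenceRecord]) -> list[PhyschemResult]:
    return [
        PhyschemResult(
            id=r.id,
            length=len(r.sequence),
            gravy=gravy(r),
            isoelectric_point=isoelectric_point(r),
        )
        for r in records
    ]


def associate_physchem(
    scores: dict[str, float], t_values: dict[str, float]
) -> tuple[float, float]:
    """Spearman rank correlation between a physchem score and t-values.

    Ids are matched by intersection; ties receive average ranks and the
    two-sided p-value uses the t approximation.  Requires at least 4 matched
    pairs and non-constant vectors.
    """
    shared = sorted(set(scores) & set(t_values))
    if len(shared) < 4:
        raise ValueError(f"need >= 4 matched ids, got {len(shared)}")
    x = [scores[i] for i in shared]
    y = [t_values[i] for i in shared]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("zero variance in one of the vectors; rho undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# FASTA support


def read_fasta(path) -> list[SequenceRecord]:
    """Plain FASTA reader; the id is the first whitespace token of the header."""
    records: list[SequenceRecord] = []
    name, chunks = None, []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks)))
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks)))
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")
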
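"""Empirical residue-pair contact potentials for complex scoring.

A family-specific statistical potential is derived from a training set of
two-chain interfaces: for every unordered residue-type pair (i, j) the
observed interchain contact count O(i,j) is compared with the count
expected from the marginal residue frequencies at those interfaces,

    E(i,j) = T * f(i) * f(j) * (2 - delta_ij),    T = total contacts,

and scored as a pseudocounted log-odds S(i,j) = ln[(O+p)/(E+p)].  Scoring
a candidate complex sums S over its interchain contacts; higher is
better.  This acts as a "biological filter": complexes whose interfaces
recapitulate the contact preferences of the training family outrank
shuffled or non-native packings.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Structure, one_letter

__all__ = [
    "AA_ALPHABET",
    "ContactDefinition",
    "PairPotentialMatrix",
    "PartitionError",
    "extract_contacts",
    "derive_matrix",
    "score_complex",
    "rank_models",
    "count_clashes",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


class PartitionError(ValueError):
    pass


class DerivationError(ValueError):
    pass


@dataclass(frozen=True)
class ContactDefinition:
    """How a residue-residue contact is declared.

    metric 'heavy' uses the minimum heavy-atom distance (default cutoff
    4.5 A); metric 'cb' uses the CB-CB distance (Gly falls back to CA;
    conventional cutoff 6.5 A).  Contacts are interchain-only by default.
    """

    metric: str = "heavy"
    cutoff: float = 4.5
    exclude_intrachain: bool = True
    min_sequence_separation: int = 4

    def __post_init__(self) -> None:
        if self.metric not in ("heavy", "cb"):
            raise ValueError(f"unknown contact metric {self.metric!r}")
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


CB_CONTACTS = ContactDefinition(metric="cb", cutoff=6.5)


def _partition_sides(structure: Structure, partition) -> tuple[list[str], list[str]]:
    side1, side2 = (list(p) for p in partition)
    if not side1 or not side2:
        raise PartitionError("both partition sides must be non-empty")
    if set(side1) & set(side2):
        raise PartitionError(f"partition sides overlap: {set(side1) & set(side2)}")
    for cid in side1 + side2:
        if cid not in structure.chains:
            raise PartitionError(f"chain {cid!r} not in structure")
    return side1, side2


def _residue_points(structure: Structure, chain_ids, metric: str):
    """Representative points per residue with an index map residue -> rows."""
    pts, owner, residues = [], [], []
    for res in structure.residues(chain_ids):
        if metric == "cb":
            atom = res.atom("CB") or res.atom("CA")
            if atom is None:
                continue
            sel = [atom]
        else:
            sel = res.atoms
        ridx = len(residues)
        residues.append(res)
        for a in sel:
            pts.append(a.coord)
            owner.append(ridx)
    return np.array(pts) if pts else np.empty((0, 3)), np.array(owner, dtype=int), residues


def contact_records(
    structure: Structure,
    partition,
    contact_def: ContactDefinition = ContactDefinition(),
) -> list[tuple]:
    """Interchain residue pairs in contact across a partition.

    Each residue *pair* appears once regardless of how many atom pairs
    fall under the cutoff; entries are (residue_side1, residue_side2).
    """
    side1, side2 = _partition_sides(structure, partition)
    p1, o1, r1 = _residue_points(structure, side1, contact_def.metric)
    p2, o2, r2 = _residue_points(structure, side2, contact_def.metric)
    if len(p1) == 0 or len(p2) == 0:
        return []
    pairs = cKDTree(p1).query_ball_tree(cKDTree(p2), contact_def.cutoff)
    seen: set[tuple[int, int]] = set()
    out = []
    for i, hits in enumerate(pairs):
        for j in hits:
            key = (o1[i], o2[j])
            if key not in seen:
                seen.add(key)
                out.append((r1[key[0]], r2[key[1]]))
    return out


def extract_contacts(
    structure: Structure,
    partition,
    contact_def: ContactDefinition = ContactDefinition(),
) -> Counter:
    """Multiset of unordered residue-type pairs in contact across a partition.

    Keys are sorted 1-letter tuples, e.g. ('E', 'K').
    """
    out: Counter = Counter()
    for ra, rb in contact_records(structure, partition, contact_def):
        a, b = one_letter(ra.name), one_letter(rb.name)
        out[tuple(sorted((a, b)))] += 1
    return out


@dataclass
class PairPotentialMatrix:
    """20x20 symmetric log-odds contact-preference matrix."""

    scores: np.ndarray
    pseudocount: float
    contact_def: ContactDefinition
    training_provenance: str = ""
    observed: np.ndarray | None = field(default=None, repr=False)
    expected: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if self.scores.shape != (20, 20):
            raise ValueError("scores must be 20x20")
        if not np.allclose(self.scores, self.scores.T):
            raise ValueError("scores must be symmetric")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[_AA_INDEX[a], _AA_INDEX[b]])

    def as_frame(self) -> pd.DataFrame:
        letters = list(AA_ALPHABET)
        return pd.DataFrame(self.scores, index=letters, columns=letters)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.as_frame().to_csv(path, sep="\t", float_format="%.6f")
        sidecar = {
            "pseudocount": self.pseudocount,
            "contact_metric": self.contact_def.metric,
            "contact_cutoff": self.contact_def.cutoff,
            "training_provenance": self.training_provenance,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairPotentialMatrix":
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", index_col=0)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        cdef = ContactDefinition(
            metric=meta.get("contact_metric", "heavy"),
            cutoff=float(meta.get("contact_cutoff", 4.5)),
        )
        scores = frame.loc[list(AA_ALPHABET), list(AA_ALPHABET)].to_numpy(float)
        scores = (scores + scores.T) / 2.0  # guard against formatting round-off
        return cls(scores, float(meta.get("pseudocount", 1.0)), cdef,
                   meta.get("training_provenance", ""))


def derive_matrix(
    training_set,
    contact_def: ContactDefinition = CB_CONTACTS,
    pseudocount: float = 1.0,
) -> PairPotentialMatrix:
    """Derive a log-odds contact matrix from (structure, partition) pairs.

    The expected count uses the marginal residue frequencies of the
    interface residues (each contact-participating residue counted once,
    pooled over the training set), so the matrix measures pairing
    preference beyond interface composition.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    observed = np.zeros((20, 20))
    participant = np.zeros(20)
    total = 0
    n_ifaces = 0
    digest = hashlib.sha256()
    for structure, partition in training_set:
        n_ifaces += 1
        records = contact_records(structure, partition, contact_def)
        seen_res: set = set()
        for k, (ra, rb) in enumerate(records):
            a, b = one_letter(ra.name), one_letter(rb.name)
            ia, ib = _AA_INDEX[a], _AA_INDEX[b]
            observed[ia, ib] += 1
            if ia != ib:
                observed[ib, ia] += 1
            total += 1
            digest.update(f"{a}{b}".encode())
            for side, res in (("1", ra), ("2", rb)):
                rk = (side, res.chain_id, res.seq_id)
                if rk not in seen_res:
                    seen_res.add(rk)
                    participant[_AA_INDEX[one_letter(res.name)]] += 1
    if n_ifaces == 0 or total == 0:
        raise DerivationError("training set contains no usable contacts")
    freqs = participant / participant.sum()
    expected = total * np.outer(freqs, freqs) * (2.0 - np.eye(20))
    # `observed` mirrors each unordered off-diagonal count into both
    # triangles, matching the symmetric form of `expected`
    scores = np.log((observed + pseudocount) / (expected + pseudocount))
    scores = (scores + scores.T) / 2.0
    return PairPotentialMatrix(
        scores,
        pseudocount,
        contact_def,
        training_provenance=(
            f"{n_ifaces} interfaces, {total} contacts, sha256:{digest.hexdigest()[:12]}"
        ),
        observed=observed,
        expected=expected,
    )


def score_complex(structure: Structure, partition, matrix: PairPotentialMatrix) -> float:
    """Sum of matrix scores over interchain contacts across the partition."""
    contacts = extract_contacts(structure, partition, matrix.contact_def)
    return float(sum(matrix.score(a, b) * n for (a, b), n in contacts.items()))


def count_clashes(structure: Structure, partition, cutoff: float = 2.5) -> int:
    """Interchain heavy-atom pairs closer than ``cutoff`` (tie-break metric)."""
    side1, side2 = _partition_sides(structure, partition)
    x1 = structure.coords(side1)
    x2 = structure.coords(side2)
    if len(x1) == 0 or len(x2) == 0:
        return 0
    return int(cKDTree(x1).count_neighbors(cKDTree(x2), cutoff))


def rank_models(models, matrix: PairPotentialMatrix):
    """Rank (structure, partition) models by pair-potential score.

    Descending score; ties broken by fewer interchain clashes (< 2.5 A),
    then by input order.  Returns a list of (structure, partition, score)
    in rank order.
    """
    if not models:
        raise ValueError("need at least one model")
    rows = []
    for k, (st, part) in enumerate(models):
        s = score_complex(st, part, matrix)
        rows.append((st, part, s, count_clashes(st, part), k))
    rows.sort(key=lambda r: (-r[2], r[3], r[4]))
    return [(st, part, s) for st, part, s, _, _ in rows]
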
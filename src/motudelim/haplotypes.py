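"""Collapse aligned accessions into haplotypes.

Two accessions share a haplotype when their sequences agree at every
retained column.  The retained columns and the meaning of "agree" are
governed by a :class:`CollapsePolicy`:

* ``drop_indel_columns`` (default on) removes every column in which any
  retained accession has a gap, matching standard practice before
  statistical-parsimony network analysis.
* ``drop_accessions_with_missing`` (default on) removes accessions whose
  sequences contain '?' anywhere.
* ``ambiguity="missing"`` (default) makes IUPAC ambiguity codes and 'N'
  non-discriminating: a site where either sequence is ambiguous cannot
  separate two haplotypes.  Because this relation is not transitive,
  accessions are assigned greedily in input order to the first compatible
  haplotype, whose representative accumulates the definite states of its
  members; ``ambiguity="state"`` compares ambiguity codes literally.

Haplotype ids are H1..Hk in order of first occurrence, so the collapse
is deterministic for a given input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import Alignment, AlignmentError, UNAMBIGUOUS
from .alignment_stats import pairwise_differences

__all__ = [
    "CollapsePolicy",
    "Haplotype",
    "HaplotypeTable",
    "collapse",
    "haplotype_distance_matrix",
]


@dataclass(frozen=True)
class CollapsePolicy:
    drop_indel_columns: bool = True
    drop_accessions_with_missing: bool = True
    ambiguity: str = "missing"  # "missing" | "state"

    def __post_init__(self):
        if self.ambiguity not in ("missing", "state"):
            raise ValueError(f"unknown ambiguity policy: {self.ambiguity}")


@dataclass
class Haplotype:
    hap_id: str
    representative: str
    members: list

    @property
    def frequency(self):
        return len(self.members)


@dataclass
class HaplotypeTable:
    haplotypes: list
    retained_columns: list
    dropped_accessions: list
    policy: CollapsePolicy

    def __len__(self):
        return len(self.haplotypes)

    @property
    def n_retained_sites(self):
        return len(self.retained_columns)

    def accession_to_haplotype(self):
        return {
            acc: h.hap_id for h in self.haplotypes for acc in h.members
        }

    def by_id(self, hap_id):
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def to_alignment(self):
        """Representatives as an alignment (over retained columns)."""
        return Alignment(
            ids=tuple(h.hap_id for h in self.haplotypes),
            seqs=tuple(h.representative for h in self.haplotypes),
        )


# gaps count as a definite fifth state when indel columns are retained;
# only ambiguity codes / 'N' / '?' are non-discriminating
DEFINITE = UNAMBIGUOUS | {"-"}


def _compatible(rep, seq):
    for a, b in zip(rep, seq):
        if a in DEFINITE and b in DEFINITE and a != b:
            return False
    return True


def _merge_rep(rep, seq):
    out = list(rep)
    for i, (a, b) in enumerate(zip(rep, seq)):
        if a not in DEFINITE and b in DEFINITE:
            out[i] = b
    return "".join(out)


def collapse(alignment, policy=CollapsePolicy()):
    """Collapse an alignment into a :class:`HaplotypeTable`."""
    ids = list(alignment.ids)
    dropped = []
    if policy.drop_accessions_with_missing:
        keep = []
        for sid in ids:
            if "?" in alignment.sequence(sid):
                dropped.append(sid)
            else:
                keep.append(sid)
        ids = keep
    if not ids:
        raise AlignmentError("no accessions remain after exclusions")

    cols = [c for c in range(alignment.length) if c not in alignment.mask]
    if policy.drop_indel_columns:
        cols = [
            c
            for c in cols
            if all(alignment.sequence(sid)[c] != "-" for sid in ids)
        ]
    if not cols:
        raise AlignmentError("no columns remain after exclusions")

    seqs = {sid: "".join(alignment.sequence(sid)[c] for c in cols) for sid in ids}

    haplotypes = []
    for sid in ids:
        seq = seqs[sid]
        placed = False
        for h in haplotypes:
            if policy.ambiguity == "state":
                match = h.representative == seq
            else:
                match = _compatible(h.representative, seq)
            if match:
                h.members.append(sid)
                if policy.ambiguity == "missing":
                    h.representative = _merge_rep(h.representative, seq)
                placed = True
                break
        if not placed:
            haplotypes.append(
                Haplotype(hap_id=f"H{len(haplotypes) + 1}", representative=seq,
                          members=[sid])
            )
    return HaplotypeTable(
        haplotypes=haplotypes,
        retained_columns=cols,
        dropped_accessions=dropped,
        policy=policy,
    )


def haplotype_distance_matrix(table):
    """Symmetric integer matrix of observed steps between representatives."""
    if not table.haplotypes:
        raise ValueError("empty haplotype table")
    n = len(table.haplotypes)
    mat = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_differences(
                table.haplotypes[i].representative,
                table.haplotypes[j].representative,
            )
            mat[i, j] = mat[j, i] = d
    return mat
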
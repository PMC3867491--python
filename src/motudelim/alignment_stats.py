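"""Character-level alignment bookkeeping.

Implements the site-count summaries used to describe a combined
multi-locus matrix: per-locus and total numbers of included, constant,
autapomorphic, parsimony-informative and variable-but-uninformative
sites, plus the mutational-step (observed difference) count between two
aligned sequences.

A column is *parsimony-informative* when at least two distinct
unambiguous states each occur in at least two sequences; *autapomorphic*
when exactly one sequence deviates from an otherwise constant column.
Gaps ('-'), missing ('?') and IUPAC ambiguity codes are not counted as
states under the default policy; ``missing_policy="strict"`` drops any
column containing such characters from the included-site count
altogether.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .treeio import AlignmentError, UNAMBIGUOUS

__all__ = [
    "SiteClassification",
    "LocusCounts",
    "apply_mask",
    "classify_sites",
    "pairwise_differences",
]


@dataclass(frozen=True)
class LocusCounts:
    included: int = 0
    constant: int = 0
    autapomorphic: int = 0
    informative: int = 0
    variable_uninformative: int = 0

    def __post_init__(self):
        parts = (
            self.constant
            + self.autapomorphic
            + self.informative
            + self.variable_uninformative
        )
        if parts != self.included:
            raise ValueError("site categories do not sum to included sites")

    def __add__(self, other):
        return LocusCounts(
            self.included + other.included,
            self.constant + other.constant,
            self.autapomorphic + other.autapomorphic,
            self.informative + other.informative,
            self.variable_uninformative + other.variable_uninformative,
        )


@dataclass(frozen=True)
class SiteClassification:
    total: LocusCounts
    per_locus: dict = field(default_factory=dict)


def apply_mask(alignment, mask=None):
    """Remove excluded columns; partitions are re-indexed.

    *mask* defaults to the alignment's own mask attribute.
    """
    if mask is None:
        mask = alignment.mask
    if not mask:
        return alignment
    return alignment.drop_columns(mask)


def _classify_column(column):
    counts = {}
    for ch in column:
        if ch in UNAMBIGUOUS:
            counts[ch] = counts.get(ch, 0) + 1
    states = len(counts)
    if states <= 1:
        return "constant"
    if sum(1 for c in counts.values() if c >= 2) >= 2:
        return "informative"
    if sum(counts.values()) - max(counts.values()) == 1:
        return "autapomorphic"
    return "variable_uninformative"


def classify_sites(alignment, missing_policy="ignore_missing"):
    """Classify every unmasked column of the alignment.

    Returns totals and, when partitions are defined, per-locus counts.
    """
    if missing_policy not in ("ignore_missing", "strict"):
        raise ValueError(f"unknown missing_policy: {missing_policy}")
    if alignment.nseq == 0 or alignment.length == 0:
        raise AlignmentError("empty alignment")

    def tally(columns):
        acc = {
            "constant": 0,
            "informative": 0,
            "autapomorphic": 0,
            "variable_uninformative": 0,
        }
        n = 0
        for c in columns:
            col = alignment.column(c)
            if missing_policy == "strict" and any(
                ch not in UNAMBIGUOUS for ch in col
            ):
                continue
            n += 1
            acc[_classify_column(col)] += 1
        return LocusCounts(
            included=n,
            constant=acc["constant"],
            autapomorphic=acc["autapomorphic"],
            informative=acc["informative"],
            variable_uninformative=acc["variable_uninformative"],
        )

    included = alignment.included_columns()
    total = tally(included)
    per_locus = {}
    for name, (s, e) in alignment.partitions.items():
        per_locus[name] = tally([c for c in included if s <= c < e])
    return SiteClassification(total=total, per_locus=per_locus)


def pairwise_differences(seq_a, seq_b, comparable_policy="unambiguous"):
    """Observed mutational steps between two aligned sequences.

    Under the default policy a column counts only when both sequences
    carry an unambiguous base there; the count is then the number of such
    comparable columns where the states differ.
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError(
            f"length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    if comparable_policy not in ("unambiguous", "all"):
        raise ValueError(f"unknown comparable_policy: {comparable_policy}")
    diffs = 0
    for a, b in zip(seq_a, seq_b):
        if comparable_policy == "unambiguous":
            if a in UNAMBIGUOUS and b in UNAMBIGUOUS and a != b:
                diffs += 1
        else:
            if a != b:
                diffs += 1
    return diffs
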
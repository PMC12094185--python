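"""Reciprocal-best-hit orthology and ortholog-mediated dataset overlap.

Orthologs are inferred as bidirectional best matches between two species'
pairwise sequence-hit tables (12-column tabular format) at an E-value cutoff
of 0.1. Cross-species dataset comparisons count, through the resulting
one-to-one ortholog map, the proteins common to two datasets, those unique
among conserved proteins, and the larger unique counts including proteins
with no detectable ortholog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from satquant.core import InvalidParameterError
from satquant.synthgen import HIT_COLUMNS


def read_hits(path) -> pd.DataFrame:
    """Read a 12-column tabular hit file (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    if (df["evalue"] < 0).any():
        raise InvalidParameterError("negative E-values in hit table")
    return df


def best_hits(hits: pd.DataFrame, evalue_max: float = 0.1) -> dict:
    """Best subject per query at the E-value cutoff.

    Among hits with evalue <= ``evalue_max``, the subject with the smallest
    E-value wins; ties are broken by higher bitscore, then lexicographically
    smaller subject id. Multiple rows for the same query/subject pair are
    collapsed to their best row first. Queries with no passing hit are
    absent from the map.
    """
    df = hits[hits["evalue"] <= evalue_max]
    if df.empty:
        return {}
    df = df.sort_values(
        ["qseqid", "evalue", "bitscore", "sseqid"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    # collapse duplicate (query, subject) rows to the best one
    df = df.drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
    best = df.drop_duplicates(subset=["qseqid"], keep="first")
    return dict(zip(best["qseqid"], best["sseqid"]))


@dataclass
class OrthologMap:
    """One-to-one ortholog pairs (id_a, id_b)."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise InvalidParameterError("ortholog map must be one-to-one")
        self.a_to_b = dict(self.pairs)
        self.b_to_a = {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["id_a", "id_b"])


def reciprocal_best(
    forward: pd.DataFrame,
    reverse: pd.DataFrame,
    evalue_max: float = 0.1,
) -> OrthologMap:
    """Bidirectional best matches between the two hit directions.

    The pair (a, b) is an ortholog call iff b is a's best forward hit and a
    is b's best reverse hit, both at the E-value cutoff. The result is
    one-to-one by construction and independent of row order.
    """
    fwd = best_hits(forward, evalue_max)
    rev = best_hits(reverse, evalue_max)
    pairs = sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)
    return OrthologMap(pairs)


@dataclass
class OverlapResult:
    """Ortholog-mediated overlap between one dataset per species.

    ``common`` lists (id_a, id_b) ortholog pairs present in both datasets.
    The *conserved* unique lists hold in-map members of one dataset whose
    partner is absent from the other; the *total* unique lists additionally
    include dataset members with no ortholog-map entry at all.
    """

    common: list[tuple[str, str]]
    only_a_conserved: list[str]
    only_b_conserved: list[str]
    only_a_total: list[str]
    only_b_total: list[str]

    @property
    def n_common_conserved(self) -> int:
        return len(self.common)

    def counts(self) -> dict:
        return {
            "n_common_conserved": len(self.common),
            "n_only_a_conserved": len(self.only_a_conserved),
            "n_only_b_conserved": len(self.only_b_conserved),
            "n_only_a_total": len(self.only_a_total),
            "n_only_b_total": len(self.only_b_total),
        }


def dataset_overlap(set_a, set_b, ortholog_map: OrthologMap) -> OverlapResult:
    """Compare two datasets (one id list per species) through the map.

    Duplicate ids are deduplicated with a warning. Both the conserved-only
    and total unique counts are reported so either Venn convention can be
    reproduced.
    """
    list_a, list_b = list(set_a), list(set_b)
    sa, sb = set(list_a), set(list_b)
    if len(sa) != len(list_a) or len(sb) != len(list_b):
        warnings.warn("duplicate ids deduplicated in dataset_overlap")
    common = sorted(
        (a, ortholog_map.a_to_b[a])
        for a in sa
        if a in ortholog_map.a_to_b and ortholog_map.a_to_b[a] in sb
    )
    common_a = {a for a, _ in common}
    common_b = {b for _, b in common}
    only_a_cons = sorted(a for a in sa if a in ortholog_map.a_to_b and a not in common_a)
    only_b_cons = sorted(b for b in sb if b in ortholog_map.b_to_a and b not in common_b)
    only_a_total = sorted(a for a in sa if a not in common_a)
    only_b_total = sorted(b for b in sb if b not in common_b)
    return OverlapResult(common, only_a_cons, only_b_cons,
                         only_a_total, only_b_total)
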
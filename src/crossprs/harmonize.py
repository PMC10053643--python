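"""Allele harmonization between discovery summary statistics and a target cohort.

Variants are matched on chromosome + position (variant IDs are not
comparable across imputation panels). For each summary-statistic variant
exactly one action is recorded:

* ``match`` — target alleles equal (A1, A2);
* ``flip_effect`` — target alleles equal (A2, A1): the target dosage counts
  the other allele, so scoring uses the effect-allele dosage ``2 - g``;
* ``excluded_palindromic`` — A/T or C/G pairs are dropped unconditionally
  (their strand cannot be resolved from allele labels, whatever the
  frequency);
* ``excluded_multiallelic`` — the target position carries more than one
  allele pair;
* ``excluded_mismatch`` — alleles incompatible even after trying the strand
  complement;
* ``excluded_absent`` — position not present in the target.

The actions partition the summary-statistic variant list exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    COMPLEMENT,
    GenotypeMatrix,
    InputError,
    SummaryStatSet,
    is_palindromic,
)

ACTION_MATCH = "match"
ACTION_FLIP = "flip_effect"
EXCLUDED_PALINDROMIC = "excluded_palindromic"
EXCLUDED_MISMATCH = "excluded_mismatch"
EXCLUDED_MULTIALLELIC = "excluded_multiallelic"
EXCLUDED_ABSENT = "excluded_absent"

ALL_ACTIONS = (
    ACTION_MATCH,
    ACTION_FLIP,
    EXCLUDED_PALINDROMIC,
    EXCLUDED_MISMATCH,
    EXCLUDED_MULTIALLELIC,
    EXCLUDED_ABSENT,
)

KEPT_ACTIONS = (ACTION_MATCH, ACTION_FLIP)


@dataclass
class HarmonizedSet:
    """Per-variant harmonization outcome.

    ``table`` has one row per summary-statistic variant with its original
    columns plus ``action``, ``target_index`` (column in the target dosage
    matrix, -1 when unmatched) and ``flip`` (True when the target dosage
    counts the non-effect allele).
    """

    table: pd.DataFrame

    def action_counts(self) -> dict:
        counts = {a: 0 for a in ALL_ACTIONS}
        counts.update(self.table["action"].value_counts().to_dict())
        return counts

    @property
    def matched(self) -> pd.DataFrame:
        """Rows usable for scoring (action match or flip_effect)."""
        return self.table[self.table["action"].isin(KEPT_ACTIONS)]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def harmonize(sumstats: SummaryStatSet, target: GenotypeMatrix) -> HarmonizedSet:
    """Resolve allele orientation of every summary-statistic variant
    against the target cohort. See the module docstring for the action
    taxonomy."""
    sumstats.validate()
    ss = sumstats.table.copy()

    tv = target.variants
    key = pd.MultiIndex.from_frame(tv[["chrom", "pos"]].astype({"pos": int}))
    dup_full = tv.duplicated(subset=["chrom", "pos", "a1", "a2"], keep=False)
    if dup_full.any():
        first = tv.loc[dup_full].iloc[0]
        raise InputError(
            "target has duplicated variants with identical alleles at "
            f"{first['chrom']}:{first['pos']}"
        )
    pos_counts = key.value_counts()
    multiallelic = set(pos_counts[pos_counts > 1].index)
    lookup = {}
    for j, (chrom, pos, a1, a2) in enumerate(
            zip(tv["chrom"], tv["pos"].astype(int), tv["a1"], tv["a2"])):
        lookup[(chrom, pos)] = (j, a1, a2)

    actions = np.empty(len(ss), dtype=object)
    target_index = np.full(len(ss), -1)
    flip = np.zeros(len(ss), dtype=bool)

    for i, (chrom, pos, a1, a2) in enumerate(
            zip(ss["chrom"], ss["pos"].astype(int), ss["a1"], ss["a2"])):
        if is_palindromic(a1, a2):
            actions[i] = EXCLUDED_PALINDROMIC
            continue
        key_i = (chrom, pos)
        if key_i in multiallelic:
            actions[i] = EXCLUDED_MULTIALLELIC
            continue
        if key_i not in lookup:
            actions[i] = EXCLUDED_ABSENT
            continue
        j, t1, t2 = lookup[key_i]
        action = _orient(a1, a2, t1, t2)
        actions[i] = action
        if action in KEPT_ACTIONS:
            target_index[i] = j
            flip[i] = action == ACTION_FLIP

    out = ss
    out["action"] = actions
    out["target_index"] = target_index
    out["flip"] = flip
    return HarmonizedSet(out)


def _orient(a1: str, a2: str, t1: str, t2: str) -> str:
    """Compare summary-stat alleles with target alleles, trying the strand
    complement before declaring a mismatch."""
    if (a1, a2) == (t1, t2):
        return ACTION_MATCH
    if (a1, a2) == (t2, t1):
        return ACTION_FLIP
    c1, c2 = COMPLEMENT.get(a1), COMPLEMENT.get(a2)
    if (c1, c2) == (t1, t2):
        return ACTION_MATCH
    if (c1, c2) == (t2, t1):
        return ACTION_FLIP
    return EXCLUDED_MISMATCH
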
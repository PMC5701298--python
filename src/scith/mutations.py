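"""Multi-region mutation catalog.

Builds the per-patient mutation table from two callers' outputs: dual-caller
consensus, base-quality / spacing / germline filters, low-VAF rescue of
known variants, GATK-style indel merging, ubiquitous/shared/private
categorization, and pyrimidine-collapsed mutation spectra with contingency
tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CallSet",
    "MutationMatrix",
    "read_caller_table",
    "consensus_calls",
    "apply_quality_filters",
    "rescue_low_vaf",
    "merge_indels",
    "build_matrix",
    "categorize_mutations",
    "mutation_spectrum",
    "spectrum_test",
    "SPECTRUM_CLASSES",
]

META_COLUMNS = ["CHROM", "POS", "REF", "ALT", "GENE", "EFFECT", "QUAL", "IS_INDEL", "CALLER"]
BASE_QUALITY_MIN = 30.0  # strict: QUAL < 30 dropped
MIN_SPACING_BP = 15  # strict: pairs closer than 15 bp dropped (both members)
RESCUE_VAF = 0.2  # strict: single-caller call kept iff VAF > 0.2

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{int(pos)}:{ref}>{alt}"


def read_caller_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _sample_columns(df: pd.DataFrame) -> list:
    skip = set(META_COLUMNS) | {"VARIANT"}
    return [c for c in df.columns if c not in skip]


def _keyed(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.index = pd.Index(
        [variant_key(c, p, r, a) for c, p, r, a in zip(df.CHROM, df.POS, df.REF, df.ALT)],
        name="variant",
    )
    return out


@dataclass
class CallSet:
    """Candidate variants with per-sample consensus presence and caller flags."""

    meta: pd.DataFrame  # indexed by variant key: CHROM POS REF ALT GENE EFFECT QUAL IS_INDEL
    presence: pd.DataFrame  # variant x sample bool (consensus, later rescued/merged)
    vaf: pd.DataFrame  # variant x sample float (NaN where neither caller called)
    called_a: pd.DataFrame  # variant x sample bool
    called_b: pd.DataFrame
    blood_called: pd.Series | None  # variant -> bool; None if no blood column

    @property
    def samples(self) -> list:
        return list(self.presence.columns)

    def subset(self, keys) -> "CallSet":
        return CallSet(
            self.meta.loc[keys],
            self.presence.loc[keys],
            self.vaf.loc[keys],
            self.called_a.loc[keys],
            self.called_b.loc[keys],
            None if self.blood_called is None else self.blood_called.loc[keys],
        )


@dataclass
class MutationMatrix:
    """Final variant x region table with categories."""

    meta: pd.DataFrame
    presence: pd.DataFrame  # bool
    vaf: pd.DataFrame
    category: pd.Series | None = field(default=None)

    @property
    def samples(self) -> list:
        return list(self.presence.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.meta.copy()
        for s in self.samples:
            out[f"present_{s}"] = self.presence[s]
            out[f"vaf_{s}"] = self.vaf[s]
        if self.category is not None:
            out["category"] = self.category
        return out


def consensus_calls(
    caller_a: pd.DataFrame, caller_b: pd.DataFrame, blood_sample: str = "blood"
) -> CallSet:
    """Intersect the two callers' SNV calls per (variant, sample).

    A variant is retained iff both callers called it in at least one common
    sample; per-sample single-caller flags are preserved for later rescue.
    Indel rows are ignored here (see merge_indels).
    """
    for name, df in (("caller_a", caller_a), ("caller_b", caller_b)):
        if (df["POS"] <= 0).any():
            raise ValueError(
                f"{name} has POS <= 0: expected 1-based VCF-style coordinates"
            )
    a = _keyed(caller_a[~caller_a["IS_INDEL"].astype(bool)])
    b = _keyed(caller_b[~caller_b["IS_INDEL"].astype(bool)])
    samples_a = [s for s in _sample_columns(a) if s != blood_sample]
    samples_b = [s for s in _sample_columns(b) if s != blood_sample]
    if samples_a != samples_b:
        raise ValueError(f"caller tables disagree on samples: {samples_a} vs {samples_b}")
    samples = samples_a
    keys = a.index.union(b.index, sort=False)
    called_a = a[samples].notna().reindex(keys, fill_value=False)
    called_b = b[samples].notna().reindex(keys, fill_value=False)
    consensus = called_a & called_b
    keep = consensus.any(axis=1)
    keys = keys[keep]
    vaf_a = a[samples].reindex(keys)
    vaf_b = b[samples].reindex(keys)
    vaf = vaf_a.combine_first(vaf_b)
    if blood_sample not in a.columns and blood_sample not in b.columns:
        blood = None
    else:
        blood_a = (
            a[blood_sample].notna() if blood_sample in a.columns else pd.Series(False, a.index)
        )
        blood_b = (
            b[blood_sample].notna() if blood_sample in b.columns else pd.Series(False, b.index)
        )
        blood = blood_a.reindex(keys, fill_value=False) | blood_b.reindex(keys, fill_value=False)
    meta_cols = [c for c in META_COLUMNS if c != "CALLER"]
    parts = [t.loc[:, meta_cols] for t in (a, b) if len(t)]
    meta = pd.concat(parts) if parts else a.loc[:, meta_cols]
    meta = meta[~meta.index.duplicated()].reindex(keys)
    return CallSet(
        meta,
        consensus.loc[keys],
        vaf,
        called_a.loc[keys],
        called_b.loc[keys],
        blood,
    )


def apply_quality_filters(
    calls: CallSet,
    min_quality: float = BASE_QUALITY_MIN,
    min_spacing: int = MIN_SPACING_BP,
    require_blood: bool = True,
) -> CallSet:
    """Base-quality, spacing and germline filters.

    Drops variants with base quality strictly below ``min_quality``; drops
    BOTH members of any same-chromosome pair closer than ``min_spacing`` bp;
    drops variants seen in the matched blood sample (germline subtraction,
    mandatory).
    """
    if require_blood and calls.blood_called is None:
        raise ValueError("germline subtraction requires a matched blood sample")
    keep = calls.meta["QUAL"] >= min_quality
    if calls.blood_called is not None:
        keep &= ~calls.blood_called.astype(bool)
    # spacing: all-pairs within chromosome; adjacent check on sorted positions
    # is equivalent for "any pair closer than min_spacing"
    meta = calls.meta
    too_close = pd.Series(False, index=meta.index)
    for _, grp in meta.groupby("CHROM", sort=False):
        ordered = grp["POS"].sort_values()
        close = ordered.diff() < min_spacing
        bad = close | close.shift(-1, fill_value=False)
        too_close.loc[ordered.index[bad]] = True
    keep &= ~too_close
    return calls.subset(meta.index[keep])


def rescue_low_vaf(calls: CallSet, vaf_threshold: float = RESCUE_VAF) -> CallSet:
    """Recover single-caller calls of variants already confirmed elsewhere.

    For a variant that is a dual-caller consensus call in >= 1 sample, any
    additional sample where only one caller detected it gains presence iff
    that sample's VAF is strictly above ``vaf_threshold``.
    """
    single = calls.called_a ^ calls.called_b
    if (single & calls.vaf.isna()).any().any():
        raise ValueError("VAF missing where caller flags claim a detection")
    eligible = calls.presence.any(axis=1)
    rescued = single & (calls.vaf > vaf_threshold) & np.asarray(eligible)[:, None]
    out = calls.subset(calls.meta.index)
    out.presence = calls.presence | rescued
    return out


def merge_indels(calls: CallSet, indel_table: pd.DataFrame | None) -> CallSet:
    """Union GATK-style indels into the final call set.

    Indels bypass the dual-caller requirement: presence = the single caller's
    calls. Rows called in blood are dropped (germline). Duplicate keys keep
    the max-quality record.
    """
    if indel_table is None or len(indel_table) == 0:
        return calls
    ind = _keyed(indel_table[indel_table["IS_INDEL"].astype(bool)])
    ind = ind.sort_values("QUAL", ascending=False)
    ind = ind[~ind.index.duplicated(keep="first")]
    blood_cols = [c for c in ("blood",) if c in ind.columns]
    if blood_cols:
        germline = ind[blood_cols[0]].notna()
        if germline.any():
            warnings.warn(
                f"dropping {int(germline.sum())} germline indel(s) found in blood",
                stacklevel=2,
            )
            ind = ind[~germline]
    samples = calls.samples
    missing = [s for s in samples if s not in ind.columns]
    if missing:
        raise ValueError(f"indel table lacks sample columns {missing}")
    ind = ind[~ind.index.isin(calls.meta.index)]
    ind_presence = ind[samples].notna()
    ind_presence = ind_presence[ind_presence.any(axis=1)]
    ind = ind.loc[ind_presence.index]
    meta_cols = [c for c in META_COLUMNS if c != "CALLER"]
    false_flags = pd.DataFrame(False, index=ind.index, columns=samples)
    return CallSet(
        pd.concat([calls.meta, ind[meta_cols]]),
        pd.concat([calls.presence, ind_presence]),
        pd.concat([calls.vaf, ind[samples]]),
        pd.concat([calls.called_a, ind[samples].notna()]),
        pd.concat([calls.called_b, false_flags]),
        None
        if calls.blood_called is None
        else pd.concat([calls.blood_called, pd.Series(False, index=ind.index)]),
    )


def build_matrix(calls: CallSet) -> MutationMatrix:
    """Finalize a CallSet into a categorized MutationMatrix."""
    retained = calls.presence.any(axis=1)
    sub = calls.subset(calls.meta.index[retained])
    matrix = MutationMatrix(sub.meta, sub.presence, sub.vaf)
    categorize_mutations(matrix)
    return matrix


def categorize_mutations(matrix: MutationMatrix) -> pd.Series:
    """Label each variant ubiquitous (all regions), shared (>=2, < all) or
    private (exactly 1). With a single region everything present is
    ubiquitous."""
    counts = matrix.presence.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("all-false presence row: drop variants upstream")
    n = len(matrix.samples)
    category = pd.Series("shared", index=matrix.presence.index, name="category")
    category[counts == n] = "ubiquitous"
    category[(counts == 1) & (counts < n)] = "private"
    matrix.category = category
    return category


def collapse_substitution(ref: str, alt: str) -> str | None:
    """Pyrimidine-collapsed 6-class label for a single-base substitution."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        return None
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def mutation_spectrum(matrix: MutationMatrix) -> pd.DataFrame:
    """Per-sample counts over the six pyrimidine-collapsed substitution classes.

    Indels are excluded; records with non-ACGT alleles are rejected with a
    warning.
    """
    snv = matrix.meta[~matrix.meta["IS_INDEL"].astype(bool)]
    counts = pd.DataFrame(0, index=matrix.samples, columns=list(SPECTRUM_CLASSES))
    for key, row in snv.iterrows():
        cls = collapse_substitution(str(row["REF"]), str(row["ALT"]))
        if cls is None:
            warnings.warn(f"skipping {key}: non-ACGT or degenerate alleles", stacklevel=2)
            continue
        present = matrix.presence.loc[key]
        counts.loc[present[present].index, cls] += 1
    return counts


def spectrum_test(
    counts: pd.DataFrame,
    mode: str = "chi2",
    focal_class: str | None = None,
    focal_group: str | None = None,
) -> tuple[float, float]:
    """Contingency test on a group x class count table.

    chi2: Pearson test on the full table (zero-margin rows/columns dropped
    with a warning). fisher: collapses to 2x2 (focal group vs rest, focal
    class vs rest) and runs the exact two-sided test.
    """
    table = counts.to_numpy(dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be nonnegative integers")
    if mode == "chi2":
        rows = table.sum(axis=1) > 0
        cols = table.sum(axis=0) > 0
        if not rows.all() or not cols.all():
            warnings.warn("dropping zero-margin rows/columns", stacklevel=2)
        table = table[rows][:, cols]
        stat, p, _, _ = stats.chi2_contingency(table)
        return float(stat), float(p)
    if mode == "fisher":
        if focal_class is None or focal_group is None:
            raise ValueError("fisher mode needs focal_class and focal_group")
        g = counts.index.get_loc(focal_group)
        c = counts.columns.get_loc(focal_class)
        a = table[g, c]
        b = table[g].sum() - a
        cc = table[:, c].sum() - a
        d = table.sum() - a - b - cc
        stat, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
        return float(stat), float(p)
    raise ValueError(f"unknown mode {mode!r}")
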
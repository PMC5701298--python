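"""Cell identity: normal diploid vs tumor vs mixture.

Combines each sorted cell's copy-number profile with targeted
mutation-validation outcomes. Cells without SCNAs and with zero validated
candidate mutations are somatic diploid; diploid-profile cells carrying more
than three candidate mutations are mixtures; SCNA cells need at least four of
the fourteen tumor-panel mutations to be confirmed as tumor; everything else
is ambiguous and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import CopyNumberProfile

__all__ = [
    "ValidationPanel",
    "CellRecord",
    "ploidy_flag",
    "classify_cell",
    "cohort_summary",
]

IDENTITIES = ("normal", "tumor", "mixture", "ambiguous")

MIXTURE_MIN_PRESENT = 4  # "> 3" candidate mutations on a diploid profile
TUMOR_MIN_PRESENT = 4  # ">= 4" of the tumor panel on an SCNA profile
DEFAULT_MIN_EVENT_SPAN = 5_000_000  # bp of contiguous non-diploid state


@dataclass
class ValidationPanel:
    """Targeted assay panels for one patient."""

    patient: str
    candidate_mutations: list  # 5-6 ubiquitous nonsynonymous variants
    tumor_panel: list  # 14 nonsynonymous variants
    outcomes: pd.DataFrame  # columns: cell, variant, outcome in {present,absent,failed}

    def __post_init__(self):
        if len(self.tumor_panel) != 14:
            raise ValueError("tumor_panel must contain exactly 14 variants")
        if len(self.candidate_mutations) not in (5, 6):
            raise ValueError("candidate panel must contain 5 or 6 variants")
        known = set(self.candidate_mutations) | set(self.tumor_panel)
        extra = set(self.outcomes["variant"]) - known
        if extra:
            raise ValueError(f"assay outcomes cover non-panel variants: {sorted(extra)[:5]}")
        bad = set(self.outcomes["outcome"]) - {"present", "absent", "failed"}
        if bad:
            raise ValueError(f"unknown assay outcomes: {sorted(bad)}")

    def present_count(self, cell: str, panel: list) -> int:
        """Validated-present count for a cell over a panel ("failed" counts as
        absent)."""
        sub = self.outcomes[
            (self.outcomes["cell"] == cell) & (self.outcomes["variant"].isin(panel))
        ]
        if sub.empty:
            raise ValueError(f"no assay outcomes for cell {cell!r}")
        return int((sub["outcome"] == "present").sum())


@dataclass
class CellRecord:
    cell_id: str
    patient: str
    region: str
    has_scna: bool
    n_present: int | None = None
    identity: str | None = field(default=None)


def ploidy_flag(
    profile: CopyNumberProfile, min_event_span: int = DEFAULT_MIN_EVENT_SPAN
) -> bool:
    """True iff some contiguous autosomal run of non-diploid bins spans
    >= min_event_span bp."""
    if profile.cn_state is None or len(profile.cn_state) == 0:
        raise ValueError("profile needs cn_state")
    grid = profile.grid
    auto = grid.autosomal
    for c, sl in grid.chrom_slices().items():
        if not auto[sl.start]:
            continue
        altered = profile.cn_state[sl] != 2
        start_bp = grid.start[sl]
        end_bp = grid.end[sl]
        run_start = None
        for i, alt in enumerate(np.append(altered, False)):
            if alt and run_start is None:
                run_start = i
            elif not alt and run_start is not None:
                if end_bp[i - 1] - start_bp[run_start] >= min_event_span:
                    return True
                run_start = None
    return False


def classify_cell(record: CellRecord, panel: ValidationPanel) -> str:
    """Assign the final identity for one cell (also stored on the record)."""
    if not record.has_scna:
        n = panel.present_count(record.cell_id, panel.candidate_mutations)
        record.n_present = n
        if n == 0:
            record.identity = "normal"
        elif n >= MIXTURE_MIN_PRESENT:
            record.identity = "mixture"
        else:
            # 1-3 validated candidates on a diploid profile: excluded
            record.identity = "ambiguous"
    else:
        n = panel.present_count(record.cell_id, panel.tumor_panel)
        record.n_present = n
        record.identity = "tumor" if n >= TUMOR_MIN_PRESENT else "ambiguous"
    return record.identity


def cohort_summary(records: list[CellRecord]) -> pd.DataFrame:
    """Identity counts by (patient, region), with per-patient totals.

    Returns a frame with one row per (patient, region) plus a "total" row per
    patient; columns are the identity classes and n_cells.
    """
    if not records:
        return pd.DataFrame(
            columns=["patient", "region", *IDENTITIES, "n_cells"]
        ).set_index(["patient", "region"])
    if any(r.identity is None for r in records):
        raise ValueError("all cells must be classified first")
    df = pd.DataFrame(
        {
            "patient": [r.patient for r in records],
            "region": [r.region for r in records],
            "identity": [r.identity for r in records],
        }
    )
    tab = (
        df.groupby(["patient", "region"])["identity"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=IDENTITIES, fill_value=0)
    )
    tab["n_cells"] = tab.sum(axis=1)
    totals = tab.groupby(level="patient").sum()
    totals.index = pd.MultiIndex.from_product([totals.index, ["total"]], names=tab.index.names)
    return pd.concat([tab, totals]).sort_index()
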
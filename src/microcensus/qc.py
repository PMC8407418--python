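"""Single-copy-gene completeness / contamination scoring and bin retention.

Completeness is the percentage of a single-copy-gene (SCG) set present at
least once in a bin; contamination is, by default, the percentage of the set
present in two or more copies (a duplication notion restricted to the set,
as in CheckM). An ``excess_copies`` variant — 100 x sum(max(copies - 1, 0))
over the set size — is available for users who prefer counting every extra
copy. Gene identifiers are matched exactly after case-folding.

The shipped default set is a 43-marker, ribosomal-protein-centric list
appropriate for CPR bacteria, which lack several of the universal bacterial
markers; it is a plain text file of identifiers and any set can be
substituted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class SCGSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("an SCG set must be non-empty")
        folded = [g.casefold() for g in self.genes]
        if len(set(folded)) != len(folded):
            dupes = [g for g, c in Counter(folded).items() if c > 1]
            raise ValueError(f"duplicate identifiers in SCG set: {dupes}")
        object.__setattr__(self, "genes", tuple(folded))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class QCReport:
    bin_id: str
    completeness: float
    contamination: float
    copy_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if not 0 <= self.contamination <= 100 or not 0 <= self.completeness <= 100:
            raise ValueError("percentages outside [0, 100]")


def load_scg_set(path: str | Path | None = None, name: str | None = None) -> SCGSet:
    """Load an SCG set from a one-identifier-per-line file (default: the
    packaged 43-marker CPR set)."""
    if path is None:
        text = (resources.files("microcensus") / "data" / "cpr_scg_43.txt").read_text()
        name = name or "cpr43"
    else:
        text = Path(path).read_text()
        name = name or Path(path).stem
    genes = tuple(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    return SCGSet(name, genes)


def score_bin(
    gene_hits: Iterable[str],
    scg_set: SCGSet,
    bin_id: str = "",
    contamination_mode: str = "multicopy_fraction",
) -> QCReport:
    """Score one bin's gene hits against an SCG set.

    ``gene_hits`` lists one identifier per detected gene copy (two rows of
    the same gene count as two copies). Identifiers outside the set are
    ignored.
    """
    if len(scg_set) == 0:
        raise ValueError("empty SCG set")
    if contamination_mode not in {"multicopy_fraction", "excess_copies"}:
        raise ValueError(f"unknown contamination_mode {contamination_mode!r}")
    members = set(scg_set.genes)
    counts = Counter(h.casefold() for h in gene_hits if h.casefold() in members)
    n = len(scg_set)
    present = sum(1 for g in scg_set.genes if counts[g] >= 1)
    if contamination_mode == "multicopy_fraction":
        contam_units = sum(1 for g in scg_set.genes if counts[g] >= 2)
    else:
        contam_units = sum(max(counts[g] - 1, 0) for g in scg_set.genes)
    return QCReport(
        bin_id=bin_id,
        completeness=100.0 * present / n,
        contamination=min(100.0 * contam_units / n, 100.0),
        copy_counts={g: counts[g] for g in scg_set.genes},
    )


def score_bins(
    hits: pd.DataFrame,
    scg_set: SCGSet,
    contamination_mode: str = "multicopy_fraction",
) -> list[QCReport]:
    """Score every bin in a gene-hit table with columns bin_id, gene_id."""
    reports = []
    for bin_id, grp in hits.groupby("bin_id", sort=True):
        reports.append(
            score_bin(grp["gene_id"].astype(str), scg_set, str(bin_id),
                      contamination_mode)
        )
    return reports


def filter_bins(
    reports: Sequence[QCReport],
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> list[str]:
    """Bins retained under the strict >min_completeness and <max_contamination
    rule (a bin at exactly 70 % complete or exactly 10 % contaminated is
    rejected)."""
    for t in (min_completeness, max_contamination):
        if not 0 <= t <= 100:
            raise ValueError(f"threshold outside [0, 100]: {t}")
    return [
        r.bin_id
        for r in reports
        if r.completeness > min_completeness and r.contamination < max_contamination
    ]


def qc_table(
    reports: Sequence[QCReport],
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> pd.DataFrame:
    retained = set(filter_bins(reports, min_completeness, max_contamination))
    return pd.DataFrame(
        [
            (r.bin_id, r.completeness, r.contamination, r.bin_id in retained)
            for r in reports
        ],
        columns=["bin_id", "completeness", "contamination", "retained"],
    ).set_index("bin_id")
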
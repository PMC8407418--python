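"""Metabolic marker flags and pathway percent-completeness per genome bin.

Matching is identifier-based: upstream annotation supplies gene symbols, EC
numbers or product strings, and the panel maps them to marker flags (e.g.
the three glycolysis genes TIM/GAPDH/PGK conserved across CPR bacteria) and
to flat pathway gene sets scored as percent of members present. Pathway
definitions carry no boolean module logic — the profile is a simple
presence census, rendered as a table or heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class MarkerPanel:
    """Presence markers (name -> alias set) and pathways (name -> gene set)."""

    markers: Mapping[str, frozenset[str]]
    pathways: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for name, aliases in self.markers.items():
            if not aliases:
                raise ValueError(f"marker {name!r} has an empty alias list")
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty member set")

    @staticmethod
    def from_tsv(path: str | Path | None = None) -> "MarkerPanel":
        """Load a panel TSV (columns kind/name/member); default packaged panel."""
        if path is None:
            text = (
                resources.files("microcensus") / "data" / "metabolic_panel.tsv"
            ).read_text()
        else:
            text = Path(path).read_text()
        markers: dict[str, set[str]] = {}
        pathways: dict[str, set[str]] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"panel line {lineno}: expected 3 columns")
            kind, name, member = (p.strip() for p in parts)
            target = {"marker": markers, "pathway": pathways}.get(kind)
            if target is None:
                raise ValueError(f"panel line {lineno}: unknown kind {kind!r}")
            target.setdefault(name, set()).add(member.casefold())
        return MarkerPanel(
            {k: frozenset(v) for k, v in markers.items()},
            {k: frozenset(v) for k, v in pathways.items()},
        )


def default_panel() -> MarkerPanel:
    return MarkerPanel.from_tsv(None)


def marker_presence(
    gene_hits: Iterable[str], panel: MarkerPanel, markers: Iterable[str] | None = None
) -> dict[str, bool]:
    """Flag each panel marker present iff any hit matches any of its aliases."""
    hits = {h.casefold() for h in gene_hits}
    names = list(markers) if markers is not None else list(panel.markers)
    unknown = [m for m in names if m not in panel.markers]
    if unknown:
        raise KeyError(f"markers not in panel: {unknown}")
    return {m: bool(hits & panel.markers[m]) for m in names}


def pathway_completeness(gene_hits: Iterable[str], definition: frozenset[str] | set[str]) -> float:
    """Percent of the pathway's member genes present; duplicates count once."""
    if not definition:
        raise ValueError("empty pathway definition")
    hits = {h.casefold() for h in gene_hits}
    members = {m.casefold() for m in definition}
    return 100.0 * len(hits & members) / len(members)


def build_profile_table(
    bin_hits: Mapping[str, Iterable[str]], panel: MarkerPanel
) -> pd.DataFrame:
    """One row per bin: marker flags then pathway percent-completeness,
    in stable (panel) column order."""
    marker_cols = list(panel.markers)
    pathway_cols = list(panel.pathways)
    rows = []
    for bin_id in sorted(bin_hits):
        hits = list(bin_hits[bin_id])
        flags = marker_presence(hits, panel)
        row: dict[str, object] = {"bin_id": bin_id}
        row.update({m: flags[m] for m in marker_cols})
        row.update(
            {p: pathway_completeness(hits, panel.pathways[p]) for p in pathway_cols}
        )
        rows.append(row)
    df = pd.DataFrame(rows, columns=["bin_id", *marker_cols, *pathway_cols])
    return df.set_index("bin_id")


def write_profile_tsv(path, table: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("# marker columns are True/False flags; pathway columns are percent completeness\n")
        table.to_csv(fh, sep="\t")


def read_profile_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="bin_id")
    for col in df.columns:
        if df[col].dtype == object and set(df[col].unique()) <= {"True", "False"}:
            df[col] = df[col] == "True"
    return df


def plot_heatmap(table: pd.DataFrame, path) -> None:
    """Grayscale heat map of the profile (flags as 0/100)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = table.astype(float)
    values = values.where(values > 1.0, values * 100.0)  # flags 0/1 -> 0/100
    fig, ax = plt.subplots(
        figsize=(1 + 0.45 * len(table.columns), 1 + 0.3 * len(table))
    )
    im = ax.imshow(values.to_numpy(), cmap="Greys", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(len(table.columns)), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(table)), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="% completeness / presence")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
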
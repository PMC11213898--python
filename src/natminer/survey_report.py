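"""Aggregation of annotations into survey tables, plus the bundled fixtures
transcribed verbatim from the study's printed tables.

The survey table is long-format: one row per (locus, protocluster)
membership pair, so a NAT gene lying in the shared region of two
protoclusters contributes two rows, matching the membership rule used for
cluster localization.  All counts are derived from this table with plain
integer arithmetic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .nat_annotate import AnnotationResult

FIXTURE_FILES = {
    "table1_fungal_bgc": "table1_fungal_bgc.tsv",
    "table2_plasmids": "table2_plasmids.tsv",
    "table3_plasmid_bgc": "table3_plasmid_bgc.tsv",
    "table4_mibig": "table4_mibig.tsv",
    "genus_class_map": "genus_class_map.tsv",
}

SURVEY_COLUMNS = [
    "domain", "phylum", "class", "genus", "species_or_strain", "replicon",
    "locus_id", "symbol", "classification", "cluster_id", "cluster_type",
]


@dataclass
class FixtureTable:
    name: str
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class SurveyTable:
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def species_count(self) -> int:
        """Distinct species/strains with at least one locus."""
        if self.df.empty:
            return 0
        return int(self.df["species_or_strain"].nunique())

    def locus_count(self) -> int:
        if self.df.empty:
            return 0
        return int(self.df["locus_id"].nunique())

    def cluster_count(self) -> int:
        if self.df.empty:
            return 0
        return int(self.df["cluster_id"].dropna().nunique())

    def loci_per_group(self, column: str) -> pd.Series:
        return self.df.drop_duplicates("locus_id")[column].value_counts()

    def clusters_per_type(self) -> pd.Series:
        sub = self.df.dropna(subset=["cluster_id"])
        return sub.drop_duplicates("cluster_id")["cluster_type"].value_counts()


def aggregate_survey(
    annotations: list[AnnotationResult],
    memberships: dict[str, list[tuple[str, str]]],
    taxa: dict[str, dict[str, str]],
) -> SurveyTable:
    """Build the long-format survey table.

    ``memberships`` maps locus_id to a list of (cluster_id, cluster_type)
    pairs; ``taxa`` maps locus_id to its taxon/replicon metadata.  A
    membership or taxon entry referencing an unknown locus is an error.
    """
    known = {a.locus_id for a in annotations}
    dangling = set(memberships) - known
    if dangling:
        raise ValueError(
            f"memberships reference unknown loci: {sorted(dangling)}"
        )
    rows = []
    for ann in annotations:
        meta = taxa.get(ann.locus_id, {})
        base = {
            "domain": meta.get("domain", ""),
            "phylum": meta.get("phylum", ""),
            "class": meta.get("class", ""),
            "genus": meta.get("genus", ""),
            "species_or_strain": meta.get("species_or_strain", ""),
            "replicon": meta.get("replicon", ""),
            "locus_id": ann.locus_id,
            "symbol": ann.assigned_symbol,
            "classification": ann.classification,
        }
        clusters = memberships.get(ann.locus_id, [])
        if not clusters:
            rows.append({**base, "cluster_id": None, "cluster_type": None})
        for cid, ctype in clusters:
            rows.append({**base, "cluster_id": cid, "cluster_type": ctype})
    return SurveyTable(pd.DataFrame(rows, columns=SURVEY_COLUMNS))


def load_fixture(name: str) -> FixtureTable:
    """Load one of the bundled tables transcribed from the printed survey
    (fungal BGCs, plasmids, plasmid BGCs, MIBiG hits, genus-to-class map)."""
    if name not in FIXTURE_FILES:
        raise ValueError(
            f"unknown fixture {name!r}; available: "
            f"{sorted(FIXTURE_FILES)}"
        )
    ref = importlib.resources.files("natminer.data") / FIXTURE_FILES[name]
    df = pd.read_csv(str(ref), sep="\t")
    if name == "table2_plasmids":
        for col in ("n_species_strains", "n_plasmids", "n_nat_genes"):
            df[col] = df[col].astype(int)
    return FixtureTable(name, df)


def fraction_by_group(
    table: SurveyTable | FixtureTable | pd.DataFrame,
    group_column: str,
    groups: list[str] | str,
    rounded: bool = False,
) -> float:
    """Percentage of table rows whose ``group_column`` value is in
    ``groups``; full precision by default, integer-rounded for display."""
    df = table.df if hasattr(table, "df") else table
    if df.empty:
        raise ValueError("cannot compute fractions of an empty table")
    if group_column not in df.columns:
        raise ValueError(f"no such column: {group_column!r}")
    if isinstance(groups, str):
        groups = [groups]
    pct = 100.0 * df[group_column].isin(groups).sum() / len(df)
    return float(round(pct)) if rounded else float(pct)


def fixture_summary() -> dict[str, float]:
    """The printed-table arithmetic: totals recomputed from the bundled
    fixtures."""
    t1 = load_fixture("table1_fungal_bgc")
    t2 = load_fixture("table2_plasmids")
    t3 = load_fixture("table3_plasmid_bgc")
    gmap = load_fixture("genus_class_map")
    klass = dict(zip(gmap.df["genus"], gmap.df["class"]))
    t1_classes = t1.df["genus"].map(klass)
    return {
        "plasmids_total": int(t2.df["n_plasmids"].sum()),
        "plasmid_nat_genes_total": int(t2.df["n_nat_genes"].sum()),
        "plasmid_genera": int(len(t2.df)),
        "fungal_bgc_entries": int(len(t1.df)),
        "fungal_bgc_eurotiomycetes": int((t1_classes == "Eurotiomycetes").sum()),
        "fungal_bgc_sordariomycetes": int((t1_classes == "Sordariomycetes").sum()),
        "plasmid_bgc_nat_genes": int(len(t3.df)),
        "mibig_nat_entries": int(len(load_fixture("table4_mibig").df)),
    }
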
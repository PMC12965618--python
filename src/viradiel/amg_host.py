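"""Conservative AMG curation rules and host-prediction summaries.

Auxiliary metabolic genes (host-derived metabolic genes carried on viral
genomes) are easily over-called; the curation chain keeps a gene only if
every rule passes:

  R1  auxiliary score 1–3 (confident AMG call);
  R2  assigned to a metabolic module and/or flagged M, K, or E
      (previously described AMG);
  R3  inside a virus region call and/or on a contig with virus score >= 0.95;
  R4  no mobile-genetic-element keyword on the contig (transposon,
      glycosyltransferase, integrase, endonuclease, ... — genes that could
      randomly import microbial metabolic genes);
  R5  if adjacent to a phage genome end, no tRNA or inverted/direct repeat
      overlap (assembly-end artifacts);
  R6  optionally, a KEGG KO must be present (pathway information).

Host summaries pool genera at or below a share threshold into "Others" and
report per-genus log2 fold changes between two sample subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .core_io import AbundanceMatrix, HostTable

__all__ = [
    "AMGRecord",
    "FilterAudit",
    "MGE_KEYWORDS",
    "load_amg_table",
    "filter_amgs",
    "packaged_fixture",
    "summarize_hosts",
    "log2_fold_change",
    "depth_exclusive_populations",
]

logger = logging.getLogger(__name__)

#: Mobile-genetic-element keyword list (case-insensitive substring match
#: over contig gene annotations): transposons, lipopolysaccharide-island
#: genes, endonucleases, integrases, plasmid stability genes.
MGE_KEYWORDS = (
    "transposon",
    "transposase",
    "glycosyltransferase",
    "nucleotidyl transferase",
    "nucleotidyltransferase",
    "carbohydrate kinase",
    "nucleotide sugar epimerase",
    "endonuclease",
    "integrase",
    "plasmid stability",
)

_RULE_NAMES = ("R1", "R2", "R3", "R4", "R5", "R6")


@dataclass(frozen=True)
class AMGRecord:
    """One annotated gene with all the evidence the rule chain consumes."""

    gene_id: str
    contig_id: str
    auxiliary_score: int
    flags: frozenset[str]
    kegg_ko: str | None
    metabolic_module: bool
    in_viral_region: bool
    contig_virus_score: float
    near_phage_end: bool
    trna_overlap: bool
    repeat_overlap: bool
    contig_keyword_hits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.auxiliary_score not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"{self.gene_id}: auxiliary_score must be 1-5, "
                f"got {self.auxiliary_score}"
            )
        if not (0.0 <= self.contig_virus_score <= 1.0):
            raise ValueError(
                f"{self.gene_id}: contig_virus_score must be in [0, 1]"
            )


@dataclass
class FilterAudit:
    """Per-gene curation verdict with the rules it failed, in rule order."""

    gene_id: str
    kept: bool
    failed_rules: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kept != (not self.failed_rules):
            raise ValueError("kept must mean no failed rules")


def _keyword_hits(text: str, keywords=MGE_KEYWORDS) -> frozenset[str]:
    low = str(text).lower()
    return frozenset(k for k in keywords if k in low)


def load_amg_table(path, keywords=MGE_KEYWORDS,
                   column_map: dict[str, str] | None = None) -> list[AMGRecord]:
    """Read a DRAM-v-style annotation TSV into :class:`AMGRecord` objects.

    Expected columns (rename via ``column_map``): gene_id, contig_id,
    auxiliary_score, flags, kegg_ko, metabolic_module, in_viral_region,
    contig_virus_score, near_phage_end, trna_overlap, repeat_overlap, and
    free-text contig_annotations scanned for the mobile-element keywords.
    Keyword hits pool per contig: one flagged gene taints every gene on
    that contig.
    """
    df = pd.read_csv(path, sep="\t", dtype={"kegg_ko": str, "flags": str})
    if column_map:
        df = df.rename(columns=column_map)
    df["kegg_ko"] = df.get("kegg_ko", pd.Series(dtype=str)).fillna("")
    df["flags"] = df.get("flags", pd.Series(dtype=str)).fillna("")
    ann = df.get("contig_annotations", pd.Series("", index=df.index)).fillna("")
    contig_hits: dict[str, frozenset[str]] = {}
    for contig, texts in ann.groupby(df["contig_id"]):
        contig_hits[contig] = _keyword_hits(" ; ".join(texts.astype(str)),
                                            keywords)
    records = []
    for row in df.itertuples(index=False):
        records.append(AMGRecord(
            gene_id=str(row.gene_id),
            contig_id=str(row.contig_id),
            auxiliary_score=int(row.auxiliary_score),
            flags=frozenset(str(row.flags)) - {" ", ""},
            kegg_ko=str(row.kegg_ko) or None,
            metabolic_module=bool(int(row.metabolic_module)),
            in_viral_region=bool(int(row.in_viral_region)),
            contig_virus_score=float(row.contig_virus_score),
            near_phage_end=bool(int(row.near_phage_end)),
            trna_overlap=bool(int(row.trna_overlap)),
            repeat_overlap=bool(int(row.repeat_overlap)),
            contig_keyword_hits=contig_hits.get(str(row.contig_id),
                                                frozenset()),
        ))
    return records


def _apply_rules(rec: AMGRecord, require_ko: bool,
                 skip_rules: frozenset[str] = frozenset()) -> list[str]:
    failed = []
    if rec.auxiliary_score not in (1, 2, 3):
        failed.append("R1")
    if not (rec.metabolic_module or rec.flags & {"M", "K", "E"}):
        failed.append("R2")
    if not (rec.in_viral_region or rec.contig_virus_score >= 0.95):
        failed.append("R3")
    if rec.contig_keyword_hits:
        failed.append("R4")
    if rec.near_phage_end and (rec.trna_overlap or rec.repeat_overlap):
        failed.append("R5")
    if require_ko and not rec.kegg_ko:
        failed.append("R6")
    return [r for r in failed if r not in skip_rules]


def filter_amgs(records: list[AMGRecord], require_ko: bool = True,
                skip_rules=()) -> tuple[list[AMGRecord], list[FilterAudit]]:
    """Run the conservative rule chain; keep genes passing every rule.

    Rules combine conjunctively; the "and/or" inside R2 and R3 is an
    inclusive OR. The audit lists every failed rule per gene, so relaxing
    any single rule (via ``skip_rules``) can only grow the kept set.
    """
    skip = frozenset(skip_rules)
    unknown = skip - set(_RULE_NAMES)
    if unknown:
        raise ValueError(f"unknown rules: {sorted(unknown)}")
    kept: list[AMGRecord] = []
    audits: list[FilterAudit] = []
    for rec in records:
        failed = _apply_rules(rec, require_ko, skip)
        audits.append(FilterAudit(gene_id=rec.gene_id, kept=not failed,
                                  failed_rules=failed))
        if not failed:
            kept.append(rec)
    return kept, audits


def packaged_fixture() -> tuple[list[AMGRecord], list[str]]:
    """The packaged 12-record fixture and its expected kept gene ids.

    The expected set was derived by applying R1–R6 (require_ko=True) by
    hand and is stored alongside the fixture.
    """
    base = resources.files("viradiel").joinpath("data")
    with resources.as_file(base.joinpath("amg_fixture.tsv")) as p:
        records = load_amg_table(p)
    expected = base.joinpath("amg_fixture_expected_kept.txt").read_text().split()
    return records, expected


# ---------------------------------------------------------------------------
# Host summaries


def summarize_hosts(matrix: AbundanceMatrix, hosts: HostTable,
                    threshold: float = 0.01,
                    included_only: bool = True) -> pd.Series:
    """Genus abundance shares with minor genera pooled into "Others".

    Sums abundance per predicted genus over all populations and samples of
    the matrix; genera whose share is at or below ``threshold`` are pooled.
    The result carries the fraction of populations with any host prediction
    in ``.attrs['predicted_fraction']``; shares sum to 1.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    cols = matrix.included_mask() if included_only else np.ones(
        len(matrix.samples), dtype=bool)
    totals: dict[str, float] = {}
    n_predicted = 0
    for pop, row in zip(matrix.population_ids, matrix.values):
        if pop not in hosts:
            continue
        n_predicted += 1
        g = hosts.genus[pop]
        totals[g] = totals.get(g, 0.0) + float(row[cols].sum())
    series = pd.Series(totals, dtype=float).sort_values(ascending=False)
    grand = series.sum()
    shares = series / grand if grand > 0 else series
    minor = shares[shares <= threshold]
    out = shares[shares > threshold]
    if len(minor):
        out = pd.concat([out, pd.Series({"Others": minor.sum()})])
    out.attrs["predicted_fraction"] = (
        n_predicted / len(matrix.population_ids) if matrix.population_ids else 0.0
    )
    out.attrs["total_abundance"] = float(grand)
    out.attrs["genus_abundance"] = totals
    return out


def log2_fold_change(summary_a: pd.Series, summary_b: pd.Series,
                     threshold: float = 0.01) -> pd.Series:
    """Per-genus log2(abundance_a / abundance_b) for major genera.

    Only genera whose combined share across the two summaries exceeds
    ``threshold`` are compared; genera absent (zero) on either side are
    excluded with a warning rather than reported as +/- infinity. Consumes
    the raw genus abundances attached by :func:`summarize_hosts`.
    """
    abund_a = summary_a.attrs["genus_abundance"]
    abund_b = summary_b.attrs["genus_abundance"]
    total = sum(abund_a.values()) + sum(abund_b.values())
    out: dict[str, float] = {}
    for genus in sorted(set(abund_a) | set(abund_b)):
        a = abund_a.get(genus, 0.0)
        b = abund_b.get(genus, 0.0)
        if total > 0 and (a + b) / total <= threshold:
            continue
        if a == 0 or b == 0:
            logger.warning("genus %s absent on one side; excluded from log2FC",
                           genus)
            continue
        out[genus] = float(np.log2(a / b))
    return pd.Series(out, dtype=float).sort_values(ascending=False)


def depth_exclusive_populations(matrix: AbundanceMatrix, layer: str) -> list[str]:
    """Populations with abundance only in ``layer``.

    Exclusive means nonzero in at least one included sample of the given
    depth layer and zero in every included sample of the other layer.
    """
    other = "DCM" if layer == "SUR" else "SUR"
    own = matrix.subset_layer(layer)
    rest = matrix.subset_layer(other)
    own_mask = own.included_mask()
    rest_mask = rest.included_mask()
    out = []
    for i, pop in enumerate(matrix.population_ids):
        if np.any(own.values[i][own_mask] > 0) and not np.any(
                rest.values[i][rest_mask] > 0):
            out.append(pop)
    return out
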
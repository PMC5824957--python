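"""Region sets, mutation annotation, and regional burden statistics.

Provides labeled genomic interval sets (0-based half-open internally; VCF
positions are converted at the boundary), a precedence-based variant
annotator standing in for a full effect predictor, an observed/expected
enrichment–depletion test, CAGE-style construction of expressed
promoter/enhancer/exon sets at basal vs. post-differentiation timepoints,
gene-set burden summaries, an exon-length-weighted resampling null for
disease-gene burden, and non-synonymous/synonymous classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .discovery import SomaticCatalog

__all__ = [
    "RegionSet",
    "GeneModel",
    "EnrichmentResult",
    "GeneSetNullResult",
    "FantomThresholds",
    "annotate_catalog",
    "enrichment_depletion",
    "build_fantom_regions",
    "regional_mutation_load",
    "gene_set_load",
    "disease_gene_null",
    "ns_s_ratio",
]

#: Annotation precedence, highest first.
ANNOTATION_PRECEDENCE = (
    "exon",
    "3_prime_UTR",
    "5_prime_UTR",
    "splice_region",
    "regulatory_region",
    "intron",
    "upstream_gene",
    "downstream_gene",
    "non_coding_transcript_exon",
    "intergenic",
)

FLANK_BP = 5000          # up/downstream gene flank, matches the extended-gene definition
SPLICE_REGION_BP = 8     # intronic bases adjacent to an exon boundary


@dataclass
class RegionSet:
    """A named set of genomic intervals, 0-based half-open.

    ``intervals`` columns: chrom, start, end, and optionally strand and
    label.  ``surveyed_length`` is the total length restricted to the
    callable genome when a callable mask was applied; otherwise the raw
    total length.
    """

    name: str
    intervals: pd.DataFrame
    surveyed_length: int | None = None
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        df = self.intervals
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"region set needs columns {sorted(required)}")
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("region intervals must satisfy start < end")
        self.intervals = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
        if self.surveyed_length is None:
            self.surveyed_length = self.total_length()

    def total_length(self) -> int:
        merged = merge_intervals(self.intervals)
        return int((merged["end"] - merged["start"]).sum()) if len(merged) else 0

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            sub = self.intervals[self.intervals["chrom"] == chrom]
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(sub["start"], sub["end"])
            )
        return self._trees[chrom]

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return bool(self._tree(chrom)[pos0])

    def count_hits(self, chroms: Sequence[str], pos0: Sequence[int]) -> int:
        return sum(1 for c, p in zip(chroms, pos0) if self.contains(c, int(p)))

    def restrict(self, mask: "RegionSet") -> "RegionSet":
        """Intersect with a callable mask; surveyed_length becomes the overlap."""
        inter = intersect_intervals(self.intervals, mask.intervals)
        return RegionSet(self.name, inter)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome."""
    if not len(df):
        return df[["chrom", "start", "end"]].copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def intersect_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection of two interval sets (merged output)."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a[a["chrom"] == chrom].to_numpy()
        tree = IntervalTree.from_tuples(
            (int(s), int(e)) for _, s, e in b[b["chrom"] == chrom].itertuples(index=False)
        )
        for _, s, e in sa:
            for iv in sorted(tree[int(s):int(e)]):
                out.append((chrom, max(int(s), iv.begin), min(int(e), iv.end)))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Portions of ``a`` not covered by ``b`` (merged output)."""
    a, b = merge_intervals(a), merge_intervals(b)
    out = []
    for chrom, sub in a.groupby("chrom", sort=True):
        bsub = b[b["chrom"] == chrom]
        tree = IntervalTree.from_tuples(
            (int(s), int(e)) for _, s, e in bsub.itertuples(index=False)
        )
        for _, s, e in sub.itertuples(index=False):
            cursor = int(s)
            for iv in sorted(tree[int(s):int(e)]):
                if iv.begin > cursor:
                    out.append((chrom, cursor, iv.begin))
                cursor = max(cursor, iv.end)
            if cursor < e:
                out.append((chrom, cursor, int(e)))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


@dataclass
class GeneModel:
    """Gene structures for annotation and codon lookup.

    ``genes``: one row per gene with chrom, start, end, strand, gene,
    coding (bool).  ``features``: exon-level rows with chrom, start, end,
    strand, gene, feature in {exon, five_utr, three_utr, nc_exon}.  CDS
    exons of coding genes carry feature == "exon"; reading frame is derived
    from cumulative CDS length in transcription order.
    """

    genes: pd.DataFrame
    features: pd.DataFrame

    def exons(self, coding_only: bool = False) -> pd.DataFrame:
        feats = self.features
        ex = feats[feats["feature"] == "exon"]
        if coding_only:
            coding = set(self.genes[self.genes["coding"]]["gene"])
            ex = ex[ex["gene"].isin(coding)]
        return ex.reset_index(drop=True)

    def extended_regions(self, flank: int = FLANK_BP) -> pd.DataFrame:
        """Extended gene regions: exons + introns + flanks (gene span padded)."""
        g = self.genes.copy()
        g["start"] = (g["start"] - flank).clip(lower=0)
        g["end"] = g["end"] + flank
        return g[["chrom", "start", "end", "strand", "gene"]]

    def introns(self) -> pd.DataFrame:
        rows = []
        for gene, sub in self.exons().groupby("gene"):
            span = self.genes[self.genes["gene"] == gene].iloc[0]
            gaps = subtract_intervals(
                pd.DataFrame([{"chrom": span["chrom"], "start": span["start"], "end": span["end"]}]),
                sub,
            )
            for _, r in gaps.iterrows():
                rows.append((r["chrom"], r["start"], r["end"], span["strand"], gene))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "gene"])


@dataclass
class EnrichmentResult:
    """Observed vs. expected mutation count in a region set."""

    region: str
    observed: int
    expected: float
    log2_ratio: float
    p: float
    direction: str  # "enrichment" | "depletion" | "none"


@dataclass
class GeneSetNullResult:
    """Empirical gene-set burden against an exon-length-weighted null."""

    empirical: int
    null_counts: np.ndarray
    z_score: float
    p: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_counts, ddof=1))


@dataclass(frozen=True)
class FantomThresholds:
    """Expression thresholds and window geometry for CAGE-defined regions.

    Enhancers: expression score >= 1 in >= 1 replicate, padded +/-100 bp.
    Promoters: score >= 30, strand-aware window of 860 bp upstream and
    100 bp downstream of the peak.
    """

    enhancer_min_score: float = 1.0
    enhancer_pad: int = 100
    promoter_min_score: float = 30.0
    promoter_upstream: int = 860
    promoter_downstream: int = 100
    replicates_required: int = 1

    def __post_init__(self):
        if min(self.enhancer_pad, self.promoter_upstream, self.promoter_downstream) < 0:
            raise ValueError("window pads must be non-negative")


# ---------------------------------------------------------------------------
# Annotation


def _build_feature_trees(gene_model: GeneModel,
                         regulatory: RegionSet | None) -> dict:
    trees: dict = {}

    def add(kind: str, chrom: str, start: int, end: int, gene: str = ""):
        if end <= start:
            return
        trees.setdefault(kind, {}).setdefault(chrom, IntervalTree())[start:end] = gene

    coding = set(gene_model.genes[gene_model.genes["coding"]]["gene"])
    for _, f in gene_model.features.iterrows():
        kind = {"exon": "exon", "five_utr": "5_prime_UTR", "three_utr": "3_prime_UTR",
                "nc_exon": "non_coding_transcript_exon"}[f["feature"]]
        add(kind, f["chrom"], int(f["start"]), int(f["end"]), f["gene"])

    for gene, sub in gene_model.features[gene_model.features["feature"] == "exon"].groupby("gene"):
        span = gene_model.genes[gene_model.genes["gene"] == gene].iloc[0]
        gaps = subtract_intervals(
            pd.DataFrame([{"chrom": span["chrom"], "start": span["start"], "end": span["end"]}]),
            sub,
        )
        for _, r in gaps.iterrows():
            s, e = int(r["start"]), int(r["end"])
            add("intron", r["chrom"], s, e, gene)
            add("splice_region", r["chrom"], s, min(e, s + SPLICE_REGION_BP), gene)
            add("splice_region", r["chrom"], max(s, e - SPLICE_REGION_BP), e, gene)

    for _, g in gene_model.genes.iterrows():
        s, e, strand = int(g["start"]), int(g["end"]), g["strand"]
        up = (max(0, s - FLANK_BP), s) if strand == "+" else (e, e + FLANK_BP)
        down = (e, e + FLANK_BP) if strand == "+" else (max(0, s - FLANK_BP), s)
        add("upstream_gene", g["chrom"], *up, g["gene"])
        add("downstream_gene", g["chrom"], *down, g["gene"])

    if regulatory is not None:
        for _, r in regulatory.intervals.iterrows():
            add("regulatory_region", r["chrom"], int(r["start"]), int(r["end"]))
    return trees


def annotate_catalog(catalog: SomaticCatalog,
                     gene_model: GeneModel,
                     regulatory: RegionSet | None = None) -> SomaticCatalog:
    """Assign each accepted variant one annotation class by fixed precedence.

    Precedence: exon > 3'UTR > 5'UTR > splice region > regulatory region >
    intron > upstream gene > downstream gene > non-coding transcript exon >
    intergenic.  Adds ``annotation`` and ``gene`` columns to the catalog
    records (rejected rows are annotated too, for audit completeness).
    """
    trees = _build_feature_trees(gene_model, regulatory)
    records = catalog.records.copy()
    annotations, genes = [], []
    for chrom, pos in zip(records["chrom"], records["pos"]):
        pos0 = int(pos) - 1
        label, gene = "intergenic", ""
        for kind in ANNOTATION_PRECEDENCE[:-1]:
            chrom_trees = trees.get(kind, {})
            hits = chrom_trees.get(chrom, IntervalTree())[pos0]
            if hits:
                label = kind
                gene = sorted(iv.data for iv in hits)[0]
                break
        annotations.append(label)
        genes.append(gene)
    records["annotation"] = annotations
    records["gene"] = genes
    return SomaticCatalog(records)


def annotation_percentages(catalog: SomaticCatalog) -> pd.DataFrame:
    """Per-clone percentage of accepted variants in each annotation class."""
    acc = catalog.accepted
    counts = acc.groupby(["clone", "annotation"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0


# ---------------------------------------------------------------------------
# Enrichment / depletion


def enrichment_depletion(catalog_positions: pd.DataFrame,
                         region: RegionSet,
                         callable_length: int,
                         direction: str = "auto") -> EnrichmentResult:
    """One-sided binomial test of observed vs. expected mutations in a region.

    ``catalog_positions`` needs columns chrom and pos (1-based).  The
    expected count assumes uniform mutation opportunity over the callable
    genome: ``expected = total * surveyed_length / callable_length``.  With
    ``direction='auto'`` the one-sided test follows the observed deviation
    (lower tail when observed < expected); ``'depletion'`` or
    ``'enrichment'`` fix the tail.  A zero observed count yields a -inf
    log2 ratio sentinel.
    """
    if callable_length <= 0:
        raise ValueError("callable_length must be positive")
    if not region.surveyed_length:
        raise ValueError("region has zero surveyed length")
    total = len(catalog_positions)
    observed = region.count_hits(
        catalog_positions["chrom"].to_numpy(),
        catalog_positions["pos"].to_numpy() - 1,
    )
    prob = region.surveyed_length / callable_length
    expected = total * prob
    if direction == "auto":
        tail = "less" if observed < expected else "greater"
    elif direction in ("depletion", "less"):
        tail = "less"
    elif direction in ("enrichment", "greater"):
        tail = "greater"
    else:
        raise ValueError(f"unknown direction {direction!r}")
    p = stats.binomtest(observed, total, prob, alternative=tail).pvalue if total else 1.0
    log2_ratio = float("-inf") if observed == 0 else float(np.log2(observed / expected))
    dir_label = "none" if observed == expected else (
        "depletion" if observed < expected else "enrichment")
    return EnrichmentResult(region.name, observed, expected, log2_ratio, p, dir_label)


# ---------------------------------------------------------------------------
# CAGE-defined expressed regions


def _expressed_ids(table: pd.DataFrame, kind: str, min_score: float,
                   replicates_required: int) -> set:
    sub = table[table["kind"] == kind]
    rep_cols = [c for c in sub.columns if c.startswith("rep")]
    n_pass = (sub[rep_cols] >= min_score).sum(axis=1)
    return set(sub.loc[n_pass >= replicates_required, "region_id"])


def _regions_for_ids(table: pd.DataFrame, ids: set, kind: str,
                     thresholds: FantomThresholds) -> pd.DataFrame:
    sub = table[(table["kind"] == kind) & table["region_id"].isin(ids)]
    rows = []
    for _, r in sub.iterrows():
        s, e = int(r["start"]), int(r["end"])
        if kind == "enhancer":
            rows.append((r["chrom"], max(0, s - thresholds.enhancer_pad),
                         e + thresholds.enhancer_pad, r.get("strand", "."), r["region_id"]))
        else:
            strand = r.get("strand", ".")
            if strand not in ("+", "-"):
                raise ValueError(
                    f"promoter peak {r['region_id']} lacks strand; window undefined")
            if strand == "+":
                rows.append((r["chrom"], max(0, s - thresholds.promoter_upstream),
                             e + thresholds.promoter_downstream, strand, r["region_id"]))
            else:
                rows.append((r["chrom"], max(0, s - thresholds.promoter_downstream),
                             e + thresholds.promoter_upstream, strand, r["region_id"]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "label"])


def build_fantom_regions(expression_tables: Mapping[str, pd.DataFrame],
                         thresholds: FantomThresholds,
                         gene_model: GeneModel) -> dict:
    """Build basal / upon-differentiation expressed region sets.

    ``expression_tables`` maps timepoint name -> table with columns
    region_id, chrom, start, end, strand, kind (enhancer|promoter), gene
    (promoters), and per-replicate score columns rep1..repN.  The first
    timepoint in sorted order is the basal (day-0) state.

    Basal = regions expressed at day 0.  Upon differentiation = regions
    expressed at any timepoint minus those expressed at day 0 (so the two
    sets are disjoint by construction).  Promoter intervals take precedence
    over enhancers where they overlap.  Exon sets contain all exons of
    genes owning an expressed promoter.
    """
    if len(expression_tables) < 2:
        raise ValueError("need at least two timepoints (basal + later)")
    timepoints = sorted(expression_tables)
    day0 = expression_tables[timepoints[0]]

    out = {}
    ids = {}
    for kind, score in (("enhancer", thresholds.enhancer_min_score),
                        ("promoter", thresholds.promoter_min_score)):
        basal_ids = _expressed_ids(day0, kind, score, thresholds.replicates_required)
        all_ids: set = set()
        for tp in timepoints:
            all_ids |= _expressed_ids(expression_tables[tp], kind, score,
                                      thresholds.replicates_required)
        ids[kind] = {"basal": basal_ids, "upon_differentiation": all_ids - basal_ids}

    promoter_gene = day0[day0["kind"] == "promoter"].set_index("region_id")["gene"].to_dict()
    exon_df = gene_model.exons()

    for phase in ("basal", "upon_differentiation"):
        prom = _regions_for_ids(day0, ids["promoter"][phase], "promoter", thresholds)
        enh = _regions_for_ids(day0, ids["enhancer"][phase], "enhancer", thresholds)
        if len(prom) and len(enh):
            trimmed = subtract_intervals(enh, prom)
            trimmed["strand"], trimmed["label"] = ".", "enhancer"
            enh = trimmed
        genes = {promoter_gene.get(i, "") for i in ids["promoter"][phase]} - {""}
        ex = exon_df[exon_df["gene"].isin(genes)][["chrom", "start", "end", "strand", "gene"]]
        ex = ex.rename(columns={"gene": "label"})
        out[(phase, "promoters")] = RegionSet(f"{phase}_promoters", prom)
        out[(phase, "enhancers")] = RegionSet(f"{phase}_enhancers", enh)
        out[(phase, "exons")] = RegionSet(f"{phase}_exons", ex)
    return out


# ---------------------------------------------------------------------------
# Regional and gene-set burden


def regional_mutation_load(catalog: SomaticCatalog,
                           region_sets: Mapping[str, RegionSet],
                           groups: Mapping[str, str]) -> dict:
    """Per-clone mutation counts (SNVs + indels) in each region set.

    Returns per-clone counts, young/old group means with SEM, old/young
    fold changes, and a two-sided Welch t-test on per-clone totals over all
    region sets (the expressed-region total).
    """
    acc = catalog.accepted
    clones = sorted(groups)
    counts = pd.DataFrame(0, index=clones, columns=list(region_sets), dtype=int)
    for clone in clones:
        sub = acc[acc["clone"] == clone]
        for name, rs in region_sets.items():
            counts.loc[clone, name] = rs.count_hits(
                sub["chrom"].to_numpy(), sub["pos"].to_numpy() - 1)
    group = pd.Series({c: groups[c] for c in clones})
    if group.nunique() < 2 or (group == "young").sum() == 0 or (group == "old").sum() == 0:
        raise ValueError("both young and old groups must be non-empty")
    means = counts.groupby(group).mean()
    sems = counts.groupby(group).sem()
    fold = means.loc["old"] / means.loc["young"].replace(0, np.nan)
    totals = counts.sum(axis=1)
    t, p = stats.ttest_ind(totals[group == "old"], totals[group == "young"],
                           equal_var=False)
    return {"counts": counts, "means": means, "sems": sems,
            "fold_old_vs_young": fold, "t_stat": float(t), "p_value": float(p)}


def gene_set_load(exonic_catalog: pd.DataFrame, gene_set: Iterable[str],
                  n_clones: int, n_genes: int | None = None) -> dict:
    """Mutation count and per-gene average for a gene set.

    ``exonic_catalog`` needs a ``gene`` column.  The average is the number
    of mutations in the set divided by (clones tested x genes in set).
    Gene symbols are case-normalized before matching.
    """
    genes = {g.upper() for g in gene_set}
    if not genes:
        raise ValueError("gene set is empty")
    if n_genes is None:
        n_genes = len(genes)
    hits = exonic_catalog["gene"].str.upper().isin(genes)
    n_hits = int(hits.sum())
    return {
        "n_mutations": n_hits,
        "mutated_genes": sorted(set(exonic_catalog.loc[hits, "gene"].str.upper())),
        "average_per_gene": n_hits / (n_clones * n_genes),
    }


def disease_gene_null(n_gene_mutations: int,
                      exons: pd.DataFrame,
                      disease_genes: Iterable[str],
                      observed_in_set: int,
                      n_resamples: int = 10_000,
                      seed: int | None = None) -> GeneSetNullResult:
    """Exon-length-weighted resampling null for disease-gene burden.

    Draws ``n_gene_mutations`` exons with replacement, with probability
    proportional to exon length, and counts how many of the drawn exons'
    genes fall in the disease set; repeated ``n_resamples`` times.  The
    observed count is compared against this null via Z-score and one-sided
    (upper-tail) empirical p-value.  Zero-length exons are excluded.
    """
    disease = {g.upper() for g in disease_genes}
    ex = exons.copy()
    ex["length"] = ex["end"] - ex["start"]
    ex = ex[ex["length"] > 0]
    if not len(ex):
        raise ValueError("no exons with positive length")
    probs = (ex["length"] / ex["length"].sum()).to_numpy()
    in_set = ex["gene"].str.upper().isin(disease).to_numpy()
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(ex), size=(n_resamples, n_gene_mutations), p=probs)
    null_counts = in_set[draws].sum(axis=1)
    mean, sd = float(null_counts.mean()), float(null_counts.std(ddof=1))
    z = (observed_in_set - mean) / sd if sd > 0 else float("nan")
    p = float((null_counts >= observed_in_set).mean())
    return GeneSetNullResult(observed_in_set, null_counts, z, p)


# ---------------------------------------------------------------------------
# Non-synonymous / synonymous ratio

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def classify_coding_snv(codon_ref: str, codon_alt: str) -> str:
    """Classify a codon substitution; stop-gain counts as non-synonymous."""
    aa_ref = CODON_TABLE[codon_ref.upper()]
    aa_alt = CODON_TABLE[codon_alt.upper()]
    return "synonymous" if aa_ref == aa_alt else "non_synonymous"


def _cds_lookup(gene_model: GeneModel, reference: Mapping[str, str]) -> dict:
    """Map (chrom, pos0) -> (codon_ref, offset_in_codon, strand) over all CDS."""
    lookup = {}
    for gene, sub in gene_model.exons(coding_only=True).groupby("gene"):
        strand = sub["strand"].iloc[0]
        sub = sub.sort_values("start", ascending=(strand == "+"))
        cds_positions = []
        for _, ex in sub.iterrows():
            rng = range(int(ex["start"]), int(ex["end"]))
            cds_positions.extend(rng if strand == "+" else reversed(rng))
        chrom = sub["chrom"].iloc[0]
        seq = reference[chrom] if isinstance(reference, Mapping) else str(reference[chrom][:])
        for i in range(0, len(cds_positions) - 2, 3):
            codon_pos = cds_positions[i:i + 3]
            bases = "".join(seq[p] for p in codon_pos).upper()
            codon = bases if strand == "+" else revcomp(bases)
            for off, p in enumerate(codon_pos):
                lookup[(chrom, p)] = (codon, off, strand)
    return lookup


def ns_s_ratio(catalog: SomaticCatalog,
               gene_model: GeneModel,
               reference: Mapping[str, str],
               groups: Mapping[str, str] | None = None) -> dict:
    """Non-synonymous/synonymous ratio of coding SNVs per clone.

    Each coding SNV is mapped to its codon (strand- and frame-aware) and
    classified via the standard codon table; stop-gains count as
    non-synonymous.  A clone with zero synonymous variants gets a NaN
    sentinel ratio.  With ``groups``, young vs. old per-clone ratios are
    compared by a two-sided Mann-Whitney test.
    """
    lookup = _cds_lookup(gene_model, reference)
    snvs = catalog.accepted_snvs()
    per_clone: dict = {}
    for _, v in snvs.iterrows():
        hit = lookup.get((v["chrom"], int(v["pos"]) - 1))
        if hit is None:
            continue
        codon_ref, off, strand = hit
        alt = v["alt"] if strand == "+" else revcomp(v["alt"])
        codon_alt = codon_ref[:off] + alt.upper() + codon_ref[off + 1:]
        kind = classify_coding_snv(codon_ref, codon_alt)
        d = per_clone.setdefault(v["clone"], {"non_synonymous": 0, "synonymous": 0})
        d[kind] += 1
    ratios = {
        c: (d["non_synonymous"] / d["synonymous"] if d["synonymous"] else float("nan"))
        for c, d in per_clone.items()
    }
    result = {"counts": per_clone, "ratios": ratios}
    if groups:
        young = [r for c, r in ratios.items() if groups.get(c) == "young" and np.isfinite(r)]
        old = [r for c, r in ratios.items() if groups.get(c) == "old" and np.isfinite(r)]
        if young and old:
            u, p = stats.mannwhitneyu(old, young, alternative="two-sided")
            result["mannwhitney_u"], result["p_value"] = float(u), float(p)
    return result
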
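"""Synthetic clone/blood sequencing data with the structure the analysis assumes.

Emulates the study design in which a single muscle stem cell is expanded
in culture to a clonal population and whole-genome sequenced alongside the
donor's blood bulk.  Three variant classes are generated per clone:

* germline heterozygotes — VAF ~0.5 in both clone and blood;
* in-vivo somatic variants — fully clonal in the expansion (true VAF 0.5),
  absent from blood, with counts scaling linearly in donor age plus a
  donor-level random effect, and trinucleotide contexts drawn from
  signature-structured spectra;
* culture-acquired variants — arising at division ``k >= 1`` of a
  synchronous binary expansion, hence present in a cell fraction ``2^-k``
  and at VAF ``2^-(k+1)`` (0.25 for a first-division mutation).

Read evidence is sampled per site and sample as Poisson depth around the
mean sequencing depth and binomial alt counts at the true VAF, with alt
reads split binomially across strands.  Caller drop-out removes each true
variant from the union callset independently with one minus the caller
sensitivity.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import VariantObservation
from .regions import GeneModel, RegionSet

__all__ = [
    "SimConfig",
    "Reference",
    "TruthSet",
    "CloneSim",
    "simulate_reference",
    "simulate_clone_trio",
    "simulate_cohort",
    "simulate_expression_table",
]

CALLERS = ("haplotypecaller", "mutect2", "fermikit")

BASES = np.array(list("ACGT"))
PYRIMIDINES = ("C", "T")
#: Alt alleles per pyrimidine ref, in canonical substitution order.
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def default_signature_profiles() -> pd.DataFrame:
    """Three generative 96-class profiles used by the simulator.

    Synthetic analogues of an age-related deamination-like process (C>T
    peaked at NpCpG), a flat clock-like process, and a C>A-dominated
    process.  Columns sum to 1; row index is the canonical 96-class order.
    """
    from .signatures import SPECTRUM_INDEX  # local import to avoid a cycle

    idx = SPECTRUM_INDEX
    profiles = pd.DataFrame(0.0, index=idx, columns=["gen1", "gen2", "gen3"])
    for label in idx:
        sub, ctx5, ctx3 = label[2:5], label[0], label[6]
        # gen1: C>T, strongly at 3' G (CpG-like)
        if sub == "C>T":
            profiles.loc[label, "gen1"] = 10.0 if ctx3 == "G" else 1.0
        # gen2: flat over everything
        profiles.loc[label, "gen2"] = 1.0
        # gen3: C>A dominated, mild 5' preference
        if sub == "C>A":
            profiles.loc[label, "gen3"] = 8.0 if ctx5 in "CT" else 4.0
        else:
            profiles.loc[label, "gen3"] += 0.2
    return profiles / profiles.sum(axis=0)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the emulated study: seven donors (three young aged
    21-24, four old aged 64-78) contributing 29 clones in total, an
    age-related accumulation of 13.1 SNVs per genome per year, 30x mean
    depth, and culture variants from a synchronous binary expansion.
    """

    genome_length: int = 1_000_000
    gc_content: float = 0.41
    n_chroms: int = 2
    n_genes: int = 20
    n_donors: int = 7
    ages: Sequence[float] = (21, 22, 24, 64, 67, 71, 78)
    clones_per_donor: Sequence[int] | int = (4, 4, 5, 4, 4, 4, 4)
    yearly_rate: float = 13.1
    intercept: float = 0.0
    donor_sd: float = 50.0
    indel_fraction: float = 0.06
    signature_weights: Sequence[float] = (0.45, 0.35, 0.20)
    n_germline_het: int = 200
    n_culture_mutations: int = 30
    culture_division_p: float = 0.5
    depth_mean: float = 30.0
    depth_dist: str = "poisson"  # "poisson" | "fixed"
    caller_sensitivity: float = 1.0
    blood_contamination: float = 0.0
    error_rate: float = 0.0
    blacklist_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")
        if not 0 < self.caller_sensitivity <= 1:
            raise ValueError("caller_sensitivity must be in (0, 1]")
        w = np.asarray(self.signature_weights, float)
        if w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ValueError("signature_weights must be non-negative and sum to 1")
        for name in ("n_genes", "n_germline_het", "n_culture_mutations"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.ages) != self.n_donors:
            raise ValueError("ages must list one age per donor")

    def clones_for_donor(self, donor_index: int) -> int:
        if isinstance(self.clones_per_donor, int):
            return self.clones_per_donor
        return int(self.clones_per_donor[donor_index])


@dataclass
class Reference:
    """Synthetic reference: sequences, gene model, and auxiliary region sets."""

    sequences: dict
    gene_model: GeneModel
    region_sets: dict
    config: SimConfig
    _context_index: dict = field(default=None, repr=False, compare=False)

    @property
    def callable_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def context_index(self) -> dict:
        """Positions per pyrimidine-collapsed trinucleotide context.

        Maps "ACA"-style collapsed contexts (center base C or T) to arrays
        of (chrom index, position) covering both strands of the genome.
        """
        if self._context_index is None:
            index: dict = {}
            chroms = sorted(self.sequences)
            for ci, chrom in enumerate(chroms):
                seq = self.sequences[chrom]
                for pos in range(1, len(seq) - 1):
                    tri = seq[pos - 1:pos + 2]
                    if tri[1] in PYRIMIDINES:
                        key = tri
                    else:
                        key = _revcomp(tri)
                    index.setdefault(key, []).append((ci, pos))
            self._context_index = {
                k: np.array(v, dtype=np.int64) for k, v in index.items()
            }
            self._chrom_names = chroms
        return self._context_index

    def chrom_names(self) -> list:
        self.context_index()
        return self._chrom_names


@dataclass
class TruthSet:
    """Ground truth for one donor's clones.

    ``variants`` columns: clone, chrom, pos (1-based), ref, alt, kind
    (germline | invivo | culture), true_vaf, division (culture variants,
    else 0), signature (generative profile of in-vivo SNVs, else ""),
    var_class (SNV | indel), detected (present in the union callset).
    """

    donor: str
    age: float
    variants: pd.DataFrame

    def of_kind(self, kind: str, clone: str | None = None) -> pd.DataFrame:
        sub = self.variants[self.variants["kind"] == kind]
        if clone is not None:
            sub = sub[sub["clone"] == clone]
        return sub

    def invivo_counts(self) -> pd.Series:
        inv = self.variants[self.variants["kind"] == "invivo"]
        return inv.groupby("clone").size()


@dataclass
class CloneSim:
    """Simulated union callset plus metadata for a single clone."""

    clone: str
    donor: str
    age: float
    observations: list
    n_invivo: int
    days_in_culture: float
    callable_fraction: float


def _rng_for(config: SimConfig, *tokens) -> np.random.Generator:
    parts = [config.seed] + [
        zlib.crc32(str(t).encode()) if not isinstance(t, (int, np.integer)) else int(t)
        for t in tokens
    ]
    return np.random.default_rng(parts)


# ---------------------------------------------------------------------------
# Reference


def simulate_reference(config: SimConfig) -> Reference:
    """Generate reference sequences, a gene model, and region sets.

    Sequences follow the configured GC content i.i.d. per base.  Genes are
    non-overlapping, strand-assigned, with CDS exons (total length a
    multiple of three), flanking UTRs for coding genes, and occasional
    non-coding genes.  A blacklist region set marks a small fraction of the
    genome as problematic.  Deterministic under ``config.seed``.
    """
    rng = _rng_for(config, "reference")
    gc = config.gc_content
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    chrom_len = config.genome_length // config.n_chroms
    sequences = {}
    for i in range(config.n_chroms):
        seq = rng.choice(BASES, size=chrom_len, p=p)
        sequences[f"chr{i + 1}"] = "".join(seq)

    genes, features = [], []
    if config.n_genes:
        slot = chrom_len // max(1, (config.n_genes // config.n_chroms + 1))
        gene_span = 6000
        if slot < gene_span + 2000:
            raise ValueError(
                f"genome too short to place {config.n_genes} non-overlapping genes")
        gi = 0
        for ci in range(config.n_chroms):
            chrom = f"chr{ci + 1}"
            n_here = config.n_genes // config.n_chroms + (
                1 if ci < config.n_genes % config.n_chroms else 0)
            for j in range(n_here):
                start = j * slot + int(rng.integers(1000, slot - gene_span - 1000))
                strand = "+" if rng.random() < 0.5 else "-"
                coding = rng.random() > 0.15
                name = f"GENE{gi + 1}"
                n_exons = int(rng.integers(3, 6))
                exon_starts = np.sort(rng.choice(
                    np.arange(0, gene_span - 400, 150), size=n_exons, replace=False))
                exons = []
                for es in exon_starts:
                    length = int(rng.integers(120, 320))
                    s, e = start + int(es), start + int(es) + length
                    if exons and s < exons[-1][1] + 30:
                        s = exons[-1][1] + 30
                        e = s + length
                    exons.append((s, e))
                # trim CDS total to a multiple of 3 so codons are well defined
                total = sum(e - s for s, e in exons)
                trim = total % 3
                if trim:
                    s, e = exons[-1]
                    exons[-1] = (s, e - trim)
                gene_start, gene_end = exons[0][0], exons[-1][1]
                genes.append((chrom, gene_start, gene_end, strand, name, coding))
                feat = "exon" if coding else "nc_exon"
                for s, e in exons:
                    features.append((chrom, s, e, strand, name, feat))
                if coding:
                    utr5 = (gene_start - 120, gene_start) if strand == "+" else (gene_end, gene_end + 120)
                    utr3 = (gene_end, gene_end + 150) if strand == "+" else (gene_start - 150, gene_start)
                    features.append((chrom, *utr5, strand, name, "five_utr"))
                    features.append((chrom, *utr3, strand, name, "three_utr"))
                gi += 1
    gene_model = GeneModel(
        genes=pd.DataFrame(genes, columns=["chrom", "start", "end", "strand", "gene", "coding"]),
        features=pd.DataFrame(features, columns=["chrom", "start", "end", "strand", "gene", "feature"]),
    )

    bl_rows = []
    n_bl = max(1, int(config.blacklist_fraction * config.genome_length / 500))
    for _ in range(n_bl):
        ci = int(rng.integers(config.n_chroms))
        s = int(rng.integers(0, chrom_len - 500))
        bl_rows.append((f"chr{ci + 1}", s, s + 500))
    blacklist = RegionSet("blacklist", pd.DataFrame(bl_rows, columns=["chrom", "start", "end"]))

    return Reference(sequences=sequences, gene_model=gene_model,
                     region_sets={"blacklist": blacklist}, config=config)


# ---------------------------------------------------------------------------
# Clone trios


def _sample_depth(rng, config: SimConfig, n: int) -> np.ndarray:
    if config.depth_dist == "fixed":
        return np.full(n, int(round(config.depth_mean)))
    return np.maximum(1, rng.poisson(config.depth_mean, size=n))


def _draw_reads(rng, config: SimConfig, vafs: np.ndarray):
    """Depth, alt, alt-forward read counts for one sample across sites."""
    depth = _sample_depth(rng, config, len(vafs))
    alt = rng.binomial(depth, np.clip(vafs, 0, 1))
    if config.error_rate > 0:
        alt = np.minimum(depth, alt + rng.binomial(depth, config.error_rate))
    alt_fwd = rng.binomial(alt, 0.5)
    return depth, alt, alt_fwd


def _place_snvs(reference: Reference, rng, n: int, weights: np.ndarray,
                profiles: pd.DataFrame):
    """Draw n SNVs with contexts from the signature mixture.

    Returns (chrom, pos1, ref, alt, signature-label) tuples.  A class
    drawn for a pyrimidine-centered site is emitted as-is; when the
    matching genomic site carries the purine on the forward strand the
    variant is reverse-complemented.
    """
    index = reference.context_index()
    chroms = reference.chrom_names()
    labels = profiles.index.to_numpy()
    sig_choice = rng.choice(len(weights), size=n, p=weights)
    mix = profiles.to_numpy()
    # draw class labels per signature in bulk, then positions per class
    label_idx = np.empty(n, dtype=np.int64)
    for sig in range(len(weights)):
        sel = sig_choice == sig
        if sel.any():
            label_idx[sel] = rng.choice(len(labels), size=int(sel.sum()), p=mix[:, sig])
    out = []
    for li in np.unique(label_idx):
        label = labels[li]
        ctx5, ref_py, alt_py, ctx3 = label[0], label[2], label[4], label[6]
        positions = index.get(ctx5 + ref_py + ctx3)
        if positions is None or not len(positions):
            continue
        which = np.flatnonzero(label_idx == li)
        picks = rng.integers(len(positions), size=len(which))
        for w, pk in zip(which, picks):
            ci, pos0 = positions[pk]
            chrom = chroms[ci]
            base = reference.sequences[chrom][pos0]
            if base in PYRIMIDINES:
                ref, alt = ref_py, alt_py
            else:
                ref, alt = _revcomp(ref_py), _revcomp(alt_py)
            out.append((chrom, int(pos0) + 1, ref, alt,
                        profiles.columns[sig_choice[w]]))
    return out


def _place_random_variants(reference: Reference, rng, n: int, indel: bool):
    chroms = reference.chrom_names()
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        seq = reference.sequences[chrom]
        pos0 = int(rng.integers(1, len(seq) - 5))
        ref_base = seq[pos0]
        if not indel:
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            out.append((chrom, pos0 + 1, ref_base, alt))
        elif rng.random() < 0.5:  # insertion
            ins = "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
            out.append((chrom, pos0 + 1, ref_base, ref_base + ins))
        else:  # deletion
            length = int(rng.integers(1, 4))
            out.append((chrom, pos0 + 1, seq[pos0:pos0 + length + 1], ref_base))
    return out


def simulate_clone_trio(config: SimConfig, reference: Reference,
                        donor: str, age: float,
                        n_clones: int | None = None,
                        profiles: pd.DataFrame | None = None):
    """Simulate union callsets for all clones of one donor, plus ground truth.

    Germline heterozygotes are shared by the donor's clones; each clone
    receives its own in-vivo somatic complement (count Poisson around
    ``intercept + yearly_rate * age`` plus a donor-level Gaussian effect
    truncated at zero) and its own culture-acquired variants.  Returns
    ``(clones, truth)`` where ``clones`` is a list of :class:`CloneSim`.

    Ages outside [0, 120] years are rejected.
    """
    if not 0 <= age <= 120:
        raise ValueError(f"age {age} outside the plausible range [0, 120]")
    rng = _rng_for(config, "trio", donor, round(age * 365))
    if profiles is None:
        profiles = default_signature_profiles()
    weights = np.asarray(config.signature_weights, float)
    if n_clones is None:
        n_clones = 3

    germline = _place_random_variants(reference, rng, config.n_germline_het, indel=False)
    donor_effect = rng.normal(0.0, config.donor_sd)

    clones, truth_rows = [], []
    for k in range(n_clones):
        clone_id = f"{donor}_c{k + 1}"
        mean_count = max(0.0, config.intercept + config.yearly_rate * age + donor_effect)
        n_invivo = int(rng.poisson(mean_count))
        n_indel = int(rng.binomial(n_invivo, config.indel_fraction))
        n_snv = n_invivo - n_indel

        snvs = _place_snvs(reference, rng, n_snv, weights, profiles)
        indels = _place_random_variants(reference, rng, n_indel, indel=True)
        culture_k = 1 + rng.geometric(config.culture_division_p, size=config.n_culture_mutations) - 1
        culture_k = np.maximum(1, culture_k)
        culture = _place_random_variants(reference, rng, config.n_culture_mutations, indel=False)

        site_rows = []
        for chrom, pos, ref, alt in germline:
            site_rows.append((chrom, pos, ref, alt, "germline", 0.5, 0.5, 0, "", "SNV"))
        for chrom, pos, ref, alt, sig in snvs:
            site_rows.append((chrom, pos, ref, alt, "invivo", 0.5,
                              config.blood_contamination, 0, sig, "SNV"))
        for chrom, pos, ref, alt in indels:
            site_rows.append((chrom, pos, ref, alt, "invivo", 0.5,
                              config.blood_contamination, 0, "", "indel"))
        for (chrom, pos, ref, alt), div in zip(culture, culture_k):
            site_rows.append((chrom, pos, ref, alt, "culture",
                              2.0 ** -(int(div) + 1), 0.0, int(div), "", "SNV"))

        sites = pd.DataFrame(site_rows, columns=[
            "chrom", "pos", "ref", "alt", "kind", "clone_vaf_true",
            "blood_vaf_true", "division", "signature", "var_class"])
        # a clone's true variants occupy distinct sites
        sites = sites.drop_duplicates(subset=["chrom", "pos"],
                                      keep="first").reset_index(drop=True)
        n_sites = len(sites)
        c_depth, c_alt, c_alt_fwd = _draw_reads(rng, config, sites["clone_vaf_true"].to_numpy())
        b_depth, b_alt, _ = _draw_reads(rng, config, sites["blood_vaf_true"].to_numpy())
        detected = rng.random(n_sites) < config.caller_sensitivity
        # variants with no alt reads in the clone cannot be called
        detected &= c_alt > 0

        observations = []
        chrom_a = sites["chrom"].to_numpy()
        pos_a = sites["pos"].to_numpy()
        ref_a = sites["ref"].to_numpy()
        alt_a = sites["alt"].to_numpy()
        caller_sets = [frozenset(CALLERS[:i + 1]) for i in range(len(CALLERS))]
        n_caller_draw = rng.integers(len(CALLERS), size=n_sites)
        for i in np.flatnonzero(detected):
            observations.append(VariantObservation(
                chrom=chrom_a[i], pos=int(pos_a[i]),
                ref=ref_a[i], alt=alt_a[i],
                clone_alt_fwd=int(c_alt_fwd[i]), clone_alt_rev=int(c_alt[i] - c_alt_fwd[i]),
                clone_depth=int(c_depth[i]), blood_alt=int(b_alt[i]),
                blood_depth=int(b_depth[i]), callers=caller_sets[n_caller_draw[i]],
                individual=donor, clone=clone_id,
            ))

        truth = sites.assign(clone=clone_id, detected=detected,
                             true_vaf=sites["clone_vaf_true"])
        truth_rows.append(truth)

        group_young = age < 40
        if group_young:
            days = float(rng.normal(52.0, 2.0))
        else:
            days = float(40.0 + 0.01 * n_invivo + rng.normal(0.0, 3.0))
        clones.append(CloneSim(
            clone=clone_id, donor=donor, age=age, observations=observations,
            n_invivo=n_invivo, days_in_culture=days,
            callable_fraction=float(np.clip(rng.normal(0.95, 0.02), 0.85, 1.0)),
        ))

    truth_df = pd.concat(truth_rows, ignore_index=True)[[
        "clone", "chrom", "pos", "ref", "alt", "kind", "true_vaf",
        "division", "signature", "var_class", "detected"]]
    return clones, TruthSet(donor=donor, age=age, variants=truth_df)


def simulate_cohort(config: SimConfig, reference: Reference | None = None):
    """Simulate the full multi-donor cohort.

    Returns ``(reference, clones, truths, metadata)`` where ``metadata`` is
    a clone-level table with donor, age, group (young < 40 years), days in
    culture, callable fraction, and the true in-vivo mutation count.
    """
    if reference is None:
        reference = simulate_reference(config)
    all_clones, truths, meta_rows = [], [], []
    for di in range(config.n_donors):
        donor = f"D{di + 1}"
        age = float(config.ages[di])
        clones, truth = simulate_clone_trio(
            config, reference, donor, age, n_clones=config.clones_for_donor(di))
        all_clones.extend(clones)
        truths.append(truth)
        for c in clones:
            meta_rows.append({
                "clone": c.clone, "donor": donor, "age": age,
                "group": "young" if age < 40 else "old",
                "days_in_culture": c.days_in_culture,
                "callable_fraction": c.callable_fraction,
                "mutation_count": c.n_invivo,
            })
    metadata = pd.DataFrame(meta_rows)
    return reference, all_clones, truths, metadata


# ---------------------------------------------------------------------------
# Expression tables


def simulate_expression_table(config: SimConfig, reference: Reference,
                              timepoints: int = 8, n_enhancers: int = 30,
                              n_replicates: int = 3) -> dict:
    """Synthetic CAGE-style expression tables per differentiation timepoint.

    Promoter peaks sit at each gene's transcription start; enhancer peaks
    are placed away from genes.  Each region is assigned one of three
    programs: basally active (expressed from day 0), differentiation-
    induced (scores exceed threshold only from a later timepoint), or
    inactive.  Returns ``{"day00": table, "day01": ...}`` with per-replicate
    score columns; deterministic under the config seed.
    """
    rng = _rng_for(config, "expression")
    genes = reference.gene_model.genes
    rows = []
    for _, g in genes.iterrows():
        tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 50
        rows.append(("prom_" + g["gene"], g["chrom"], tss, tss + 50,
                     g["strand"], "promoter", g["gene"]))
    chrom_names = sorted(reference.sequences)
    for i in range(n_enhancers):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        s = int(rng.integers(0, len(reference.sequences[chrom]) - 300))
        rows.append((f"enh_{i + 1}", chrom, s, s + 200, ".", "enhancer", ""))
    base = pd.DataFrame(rows, columns=[
        "region_id", "chrom", "start", "end", "strand", "kind", "gene"])

    program = rng.choice(["basal", "induced", "off"], size=len(base), p=[0.4, 0.35, 0.25])
    onset = rng.integers(1, max(2, timepoints), size=len(base))
    # guarantee both phases are represented for each region kind
    for kind in ("promoter", "enhancer"):
        idx = np.flatnonzero(base["kind"].to_numpy() == kind)
        if len(idx) >= 2:
            program[idx[0]] = "basal"
            program[idx[1]], onset[idx[1]] = "induced", 1
    tables = {}
    for t in range(timepoints):
        day = f"day{t:02d}"
        tab = base.copy()
        high = np.where(tab["kind"] == "promoter", 60.0, 4.0)
        low = np.where(tab["kind"] == "promoter", 5.0, 0.2)
        active = (program == "basal") | ((program == "induced") & (t >= onset))
        for r in range(n_replicates):
            noise = rng.lognormal(0.0, 0.25, size=len(tab))
            tab[f"rep{r + 1}"] = np.where(active, high, low) * noise
        tables[day] = tab
    return tables
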
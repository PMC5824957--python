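"""Somatic variant discovery from clone vs. blood callsets.

A clonal population grown from a single cell carries that founder cell's
in-vivo somatic mutations at an allele fraction of ~0.5 (heterozygous in
every cell), while mutations acquired during the in-vitro expansion are
subclonal (VAF <= 0.25) and germline variants are shared with the matched
blood bulk.  The filter chain implemented here exploits exactly these
properties: a clone-VAF window around 0.5, a blood-VAF ceiling, depth and
strand-support requirements, a problematic-region blacklist, exclusion of
the sex chromosomes, and removal of variants recurring across individuals.

The module also estimates the pipeline's false negative rate from germline
heterozygous control sites and applies the corresponding burden correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantObservation",
    "FilterParams",
    "SomaticCatalog",
    "FnrResult",
    "union_callsets",
    "filter_somatic",
    "estimate_fnr",
    "correct_for_fnr",
    "normalize_burden",
]

SEX_CHROMS = {"X", "Y", "chrX", "chrY"}

#: Rejection reasons in the fixed evaluation order of the filter chain.
REJECTION_ORDER = (
    "clone_vaf",
    "blood_vaf",
    "min_coverage",
    "sex_chromosome",
    "strand_support",
    "max_coverage",
    "blacklist",
    "recurrent_across_individuals",
)


@dataclass(frozen=True)
class VariantObservation:
    """One candidate variant with per-sample read evidence.

    Coordinates are 1-based (VCF convention).  ``callers`` records which
    callers contributed the variant to the union callset.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    clone_alt_fwd: int
    clone_alt_rev: int
    clone_depth: int
    blood_alt: int
    blood_depth: int
    callers: frozenset = frozenset()
    individual: str = ""
    clone: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not (0 <= self.clone_alt <= self.clone_depth):
            raise ValueError("clone alt reads outside [0, depth]")
        if not (0 <= self.blood_alt <= self.blood_depth):
            raise ValueError("blood alt reads outside [0, depth]")

    @property
    def clone_alt(self) -> int:
        return self.clone_alt_fwd + self.clone_alt_rev

    @property
    def clone_vaf(self) -> float:
        return self.clone_alt / self.clone_depth if self.clone_depth else float("nan")

    @property
    def blood_vaf(self) -> float:
        return self.blood_alt / self.blood_depth if self.blood_depth else float("nan")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the somatic filter chain.

    Defaults: clone VAF in the closed window [0.4, 0.6]; blood VAF
    strictly below 0.1; at least 15x coverage in both clone and blood; at
    most 1000x in the clone; alt-supporting reads on both strands; sex
    chromosomes excluded.
    """

    vaf_window: tuple = (0.4, 0.6)
    blood_vaf_max: float = 0.1
    min_depth: int = 15
    max_depth: int = 1000
    require_both_strands: bool = True
    blacklist: "RegionSet | None" = None
    exclude_sex_chroms: bool = True

    def __post_init__(self):
        lo, hi = self.vaf_window
        if not (0 <= lo <= hi <= 1):
            raise ValueError("VAF window must satisfy 0 <= lower <= upper <= 1")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must not exceed max_depth")


@dataclass
class FnrResult:
    """False-negative-rate estimate from germline control sites.

    ``fnr = 1 - positive_prediction_rate``, where the positive prediction
    rate is the fraction of control sites passing their respective check
    (heterozygous sites: detected with clone VAF inside the somatic window;
    homozygous sites: blood minor-allele fraction below the blood ceiling).
    """

    n_control_sites: int
    n_detected_in_window: int
    positive_prediction_rate: float
    fnr: float
    het_pass_rate: float = float("nan")
    hom_pass_rate: float = float("nan")


@dataclass
class SomaticCatalog:
    """Filtered somatic variants with a per-candidate audit trail.

    ``records`` holds one row per candidate with columns ``clone``,
    ``individual``, ``chrom``, ``pos``, ``ref``, ``alt``, ``var_class``
    (SNV/indel), ``clone_vaf``, ``blood_vaf``, ``accepted`` and ``reason``
    (first failing criterion, empty for accepted variants).  Optional
    annotation columns (``context``, ``annotation``, ``gene``, ``score``)
    are added by downstream stages.
    """

    records: pd.DataFrame

    @property
    def accepted(self) -> pd.DataFrame:
        return self.records[self.records["accepted"]]

    @property
    def rejected(self) -> pd.DataFrame:
        return self.records[~self.records["accepted"]]

    def accepted_snvs(self) -> pd.DataFrame:
        acc = self.accepted
        return acc[acc["var_class"] == "SNV"]

    def counts_per_clone(self, var_class: str | None = None) -> pd.Series:
        acc = self.accepted
        if var_class is not None:
            acc = acc[acc["var_class"] == var_class]
        return acc.groupby("clone").size()

    def rejection_summary(self) -> pd.Series:
        return self.rejected.groupby("reason").size()


def union_callsets(per_caller_callsets: Mapping[str, Iterable[VariantObservation]]):
    """Union per-caller callsets into a candidate list with provenance.

    Variants are keyed by (chrom, pos, ref, alt); the returned observations
    carry the set of callers that reported each variant.  Conflicting read
    evidence for the same key raises, as the callsets are expected to be
    derived from a single pileup.

    Returns a list sorted by genomic position.
    """
    merged: dict = {}
    for caller, callset in per_caller_callsets.items():
        for obs in callset:
            key = (obs.individual, obs.clone) + obs.key
            ref_key = (obs.individual, obs.clone, obs.chrom, obs.pos)
            prev = merged.get(key)
            if prev is None:
                for other in merged:
                    if other[:4] == ref_key[:2] + ref_key[2:] and other[4] != obs.ref:
                        raise ValueError(
                            f"conflicting ref alleles at {obs.chrom}:{obs.pos}"
                        )
                merged[key] = replace(obs, callers=frozenset({caller}))
            else:
                merged[key] = replace(prev, callers=prev.callers | {caller})
    return sorted(merged.values(), key=lambda o: (o.individual, o.clone, o.chrom, o.pos, o.alt))


def pool_interesting_positions(candidates: Iterable[VariantObservation]):
    """Pool candidate positions across all clones of each individual.

    Returns ``{individual: {(chrom, pos, ref, alt), ...}}`` — the
    comprehensive per-individual list of positions at which every clone of
    that individual is subsequently re-examined.
    """
    pooled: dict = {}
    for obs in candidates:
        pooled.setdefault(obs.individual, set()).add(obs.key)
    return pooled


def _first_failure(obs: VariantObservation, params: FilterParams,
                   recurrent_keys: set) -> str | None:
    lo, hi = params.vaf_window
    if not (lo <= obs.clone_vaf <= hi):
        return "clone_vaf"
    if not (obs.blood_vaf < params.blood_vaf_max):
        return "blood_vaf"
    if obs.clone_depth < params.min_depth or obs.blood_depth < params.min_depth:
        return "min_coverage"
    if params.exclude_sex_chroms and obs.chrom in SEX_CHROMS:
        return "sex_chromosome"
    if params.require_both_strands and (obs.clone_alt_fwd < 1 or obs.clone_alt_rev < 1):
        return "strand_support"
    if obs.clone_depth > params.max_depth:
        return "max_coverage"
    if params.blacklist is not None and params.blacklist.contains(obs.chrom, obs.pos - 1):
        return "blacklist"
    if obs.key in recurrent_keys:
        return "recurrent_across_individuals"
    return None


def filter_somatic(candidates: Sequence[VariantObservation],
                   params: FilterParams | None = None,
                   cross_individual_index: Mapping | None = None) -> SomaticCatalog:
    """Apply the somatic filter chain to a candidate list.

    A candidate is accepted iff its clone VAF lies in the window, its blood
    VAF is below the ceiling, both samples meet the depth floor, the clone
    does not exceed the depth cap, alt reads occur on both strands, it is
    not on a sex chromosome, not in the blacklist, and not detected in more
    than one individual.  Each rejected candidate records the first failing
    criterion in the fixed evaluation order.

    ``cross_individual_index`` maps (chrom, pos, ref, alt) to the set of
    individuals in which the variant was observed; when absent it is built
    from the candidates themselves.
    """
    params = params or FilterParams()
    for obs in candidates:
        if obs.blood_depth == 0 and obs.clone_depth == 0:
            raise ValueError(
                f"candidate {obs.chrom}:{obs.pos} lacks read evidence; "
                "a matched blood bulk is required"
            )
    if cross_individual_index is None:
        cross_individual_index = {}
        for obs in candidates:
            cross_individual_index.setdefault(obs.key, set()).add(obs.individual)
    recurrent = {k for k, inds in cross_individual_index.items() if len(inds) > 1}

    rows = []
    for obs in candidates:
        reason = _first_failure(obs, params, recurrent)
        rows.append({
            "clone": obs.clone,
            "individual": obs.individual,
            "chrom": obs.chrom,
            "pos": obs.pos,
            "ref": obs.ref,
            "alt": obs.alt,
            "var_class": "SNV" if obs.is_snv else "indel",
            "clone_vaf": obs.clone_vaf,
            "blood_vaf": obs.blood_vaf,
            "clone_alt_fwd": obs.clone_alt_fwd,
            "clone_alt_rev": obs.clone_alt_rev,
            "clone_depth": obs.clone_depth,
            "blood_alt": obs.blood_alt,
            "blood_depth": obs.blood_depth,
            "callers": ",".join(sorted(obs.callers)),
            "accepted": reason is None,
            "reason": reason or "",
        })
    columns = ["clone", "individual", "chrom", "pos", "ref", "alt", "var_class",
               "clone_vaf", "blood_vaf", "clone_alt_fwd", "clone_alt_rev",
               "clone_depth", "blood_alt", "blood_depth", "callers",
               "accepted", "reason"]
    return SomaticCatalog(pd.DataFrame(rows, columns=columns))


def estimate_fnr(het_controls: pd.DataFrame,
                 hom_controls: pd.DataFrame | None = None,
                 vaf_window: tuple = (0.4, 0.6),
                 blood_vaf_max: float = 0.1,
                 min_depth: int = 15) -> FnrResult:
    """Estimate the false negative rate from germline control sites.

    ``het_controls``: germline heterozygous SNVs with columns ``clone_alt``,
    ``clone_depth`` and ``detected`` (seen by at least one caller in the
    clone).  A het control passes when it is detected and its clone VAF
    falls inside the somatic discovery window.  ``hom_controls`` (optional):
    germline homozygous SNVs with columns ``blood_minor`` and
    ``blood_depth``; a hom control passes when its blood minor-allele
    fraction is below the blood ceiling.  The positive prediction rate is
    the pooled fraction of passing controls over both sets and the FNR its
    complement.  Sites below the depth floor are excluded upfront.
    """
    het = het_controls[het_controls["clone_depth"] >= min_depth]
    n_het = len(het)
    lo, hi = vaf_window
    vaf = het["clone_alt"] / het["clone_depth"]
    het_pass = het["detected"].to_numpy(bool) & (vaf >= lo).to_numpy() & (vaf <= hi).to_numpy()
    n_het_pass = int(het_pass.sum())

    n_hom = n_hom_pass = 0
    if hom_controls is not None and len(hom_controls):
        hom = hom_controls[hom_controls["blood_depth"] > 0]
        n_hom = len(hom)
        maf = hom["blood_minor"] / hom["blood_depth"]
        n_hom_pass = int((maf < blood_vaf_max).sum())

    total = n_het + n_hom
    if total == 0:
        raise ValueError("no control sites passed the depth requirement; FNR undefined")
    ppr = (n_het_pass + n_hom_pass) / total
    return FnrResult(
        n_control_sites=total,
        n_detected_in_window=n_het_pass + n_hom_pass,
        positive_prediction_rate=ppr,
        fnr=1.0 - ppr,
        het_pass_rate=n_het_pass / n_het if n_het else float("nan"),
        hom_pass_rate=n_hom_pass / n_hom if n_hom else float("nan"),
    )


def correct_for_fnr(observed: int, fnr: float) -> int:
    """Correct an observed mutation count for the false negative rate.

    Returns ``floor(observed / (1 - fnr))`` — e.g. 209 observed SNVs at an
    FNR of 0.41 correspond to an estimated 354 true mutations.
    """
    if not (0 <= fnr < 1):
        raise ValueError("fnr must lie in [0, 1)")
    return math.floor(observed / (1.0 - fnr))


def normalize_burden(count: float, callable_fraction: float) -> float:
    """Normalize a mutation count to the fraction of autosomes covered.

    ``callable_fraction`` may also be a callable length in gigabases to
    obtain per-Gb rates.
    """
    if callable_fraction <= 0:
        raise ValueError("callable fraction must be positive")
    return count / callable_fraction
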
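"""Readers and writers for the interchange formats.

VCF v4.2 carries the per-sample read evidence (FORMAT ``GT:AD:DP:SAC``,
where ``SAC`` lists ref-forward, ref-reverse, alt-forward, alt-reverse
counts); BED files are 0-based half-open; TSV holds metadata, expression
tables, truth sets and audit tables.  Positions are 1-based inside VCF and
converted at the boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .discovery import SomaticCatalog, VariantObservation
from .regions import RegionSet

__all__ = [
    "write_reference_fasta",
    "read_reference_fasta",
    "write_callset_vcf",
    "read_callset",
    "read_regions",
    "write_regions",
    "write_catalog",
    "read_catalog_tsv",
    "write_table",
    "read_table",
]

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=SAC,Number=4,Type=Integer,Description="Strand allele counts: ref-fwd,ref-rev,alt-fwd,alt-rev">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting the variant">
"""


def write_reference_fasta(sequences: Mapping[str, str], path) -> Path:
    """Write chromosome sequences as FASTA, 60 columns per line."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    return path


def read_reference_fasta(path) -> dict:
    """Read a FASTA into {chrom: sequence} via pyfaidx."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# VCF


def _split_strands(alt: int) -> tuple:
    return (alt - alt // 2, alt // 2)


def write_callset_vcf(observations: Sequence[VariantObservation], path,
                      clone_sample: str | None = None,
                      blood_sample: str = "blood",
                      contigs: Mapping[str, int] | None = None) -> Path:
    """Write a clone+blood union callset as a two-sample VCF.

    Clone strand counts are carried in ``SAC``; blood alt reads are split
    evenly across strands (the filter only uses clone strand evidence).
    """
    path = Path(path)
    obs = sorted(observations, key=lambda o: (o.chrom, o.pos, o.alt))
    if clone_sample is None:
        clone_sample = obs[0].clone if obs else "clone"
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        if contigs:
            for name in sorted(contigs):
                fh.write(f"##contig=<ID={name},length={contigs[name]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{clone_sample}\t{blood_sample}\n")
        for o in obs:
            c_ref = o.clone_depth - o.clone_alt
            b_ref = o.blood_depth - o.blood_alt
            b_fwd, b_rev = _split_strands(o.blood_alt)
            info = "CALLERS=" + ",".join(sorted(o.callers)) if o.callers else "."
            clone_col = (f"0/1:{c_ref},{o.clone_alt}:{o.clone_depth}:"
                         f"{c_ref - c_ref // 2},{c_ref // 2},{o.clone_alt_fwd},{o.clone_alt_rev}")
            blood_col = (f"0/0:{b_ref},{o.blood_alt}:{o.blood_depth}:"
                         f"{b_ref - b_ref // 2},{b_ref // 2},{b_fwd},{b_rev}")
            fh.write(f"{o.chrom}\t{o.pos}\t.\t{o.ref}\t{o.alt}\t.\t.\t{info}\t"
                     f"GT:AD:DP:SAC\t{clone_col}\t{blood_col}\n")
    return path


def read_callset(path, clone_sample: str, blood_sample: str,
                 individual: str = "", clone: str | None = None) -> list:
    """Read a multi-sample VCF into VariantObservation records.

    Requires per-sample ``AD`` and ``DP``; multi-allelic records are
    decomposed into one observation per alt allele.  When the ``SAC``
    strand counts are absent, clone alt reads are split evenly across
    strands with a warning — the strand criterion is then uninformative and
    should be disabled in :class:`~clonesoma.discovery.FilterParams`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in (clone_sample, blood_sample):
        if s not in samples:
            raise ValueError(f"sample {s!r} not present in {path} (has {samples})")
    ci, bi = samples.index(clone_sample), samples.index(blood_sample)
    clone_id = clone if clone is not None else clone_sample

    observations = []
    warned = False
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks the AD field")
        dp = rec.format("DP")
        sac = rec.format("SAC")
        callers = frozenset()
        info_callers = rec.INFO.get("CALLERS")
        if info_callers:
            callers = frozenset(str(info_callers).split(","))
        for ai, alt in enumerate(rec.ALT):
            clone_alt = int(ad[ci][ai + 1]) if ad.shape[1] > ai + 1 else 0
            blood_alt = int(ad[bi][ai + 1]) if ad.shape[1] > ai + 1 else 0
            clone_alt = max(0, clone_alt)
            blood_alt = max(0, blood_alt)
            clone_depth = int(dp[ci][0]) if dp is not None else int(np.sum(np.maximum(ad[ci], 0)))
            blood_depth = int(dp[bi][0]) if dp is not None else int(np.sum(np.maximum(ad[bi], 0)))
            if sac is not None and len(rec.ALT) == 1 and sac.shape[1] == 4:
                fwd, rev = int(sac[ci][2]), int(sac[ci][3])
                if fwd + rev != clone_alt:  # stale counts; fall back to even split
                    fwd, rev = _split_strands(clone_alt)
            else:
                if not warned:
                    warnings.warn(
                        "SAC strand counts unavailable; alt reads split evenly — "
                        "disable require_both_strands for this callset")
                    warned = True
                fwd, rev = _split_strands(clone_alt)
            observations.append(VariantObservation(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                clone_alt_fwd=fwd, clone_alt_rev=rev,
                clone_depth=max(clone_depth, clone_alt),
                blood_alt=blood_alt, blood_depth=max(blood_depth, blood_alt),
                callers=callers, individual=individual, clone=clone_id))
    return observations


# ---------------------------------------------------------------------------
# BED


def read_regions(path, name: str | None = None) -> RegionSet:
    """Read a BED file (0-based half-open) into a RegionSet.

    Columns beyond chrom/start/end are taken as label and strand when
    present.  Malformed lines raise with their line number.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: start must be < end")
            row = {"chrom": parts[0], "start": start, "end": end}
            if len(parts) > 3:
                row["label"] = parts[3]
            if len(parts) > 5:
                row["strand"] = parts[5]
            rows.append(row)
    return RegionSet(name or path.stem, pd.DataFrame(
        rows, columns=["chrom", "start", "end", "label", "strand"]
    ).dropna(axis=1, how="all") if rows else pd.DataFrame(
        columns=["chrom", "start", "end"]))


def write_regions(region_set: RegionSet, path) -> Path:
    path = Path(path)
    df = region_set.intervals
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            cols = [str(r["chrom"]), str(int(r["start"])), str(int(r["end"]))]
            if "label" in df.columns or "strand" in df.columns:
                cols += [str(r.get("label", ".")), "0", str(r.get("strand", "."))]
            fh.write("\t".join(cols) + "\n")
    return path


# ---------------------------------------------------------------------------
# Catalog and generic tables


def write_catalog(catalog: SomaticCatalog, vcf_path=None, tsv_path=None) -> None:
    """Write the accepted variants as VCF and the full audit table as TSV."""
    if tsv_path is not None:
        catalog.records.to_csv(tsv_path, sep="\t", index=False)
    if vcf_path is not None:
        obs = []
        for _, r in catalog.accepted.iterrows():
            obs.append(VariantObservation(
                chrom=r["chrom"], pos=int(r["pos"]), ref=r["ref"], alt=r["alt"],
                clone_alt_fwd=int(r["clone_alt_fwd"]), clone_alt_rev=int(r["clone_alt_rev"]),
                clone_depth=int(r["clone_depth"]), blood_alt=int(r["blood_alt"]),
                blood_depth=int(r["blood_depth"]),
                callers=frozenset(str(r["callers"]).split(",")) if r["callers"] else frozenset(),
                individual=r["individual"], clone=r["clone"]))
        write_callset_vcf(obs, vcf_path)


def read_catalog_tsv(path) -> SomaticCatalog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"reason": str, "callers": str, "clone": str,
                            "individual": str, "chrom": str})
    df["accepted"] = df["accepted"].astype(bool)
    return SomaticCatalog(df)


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
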
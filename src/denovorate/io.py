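"""Reading and writing trio-cohort data: VCF, PED, ages, depth tracks.

The in-memory model is a :class:`Cohort`: per-site genotype/quality arrays
over a fixed sample ordering (child, father, mother for each family), with a
variant table and optional per-site read-level statistics used by the
cohort-level site filter.  Individual sites can be materialised as
:class:`SiteRecord` objects for record-oriented code; the array layout exists
so that calling and calibration over tens of thousands of sites stay fast.

Coordinates follow the VCF convention (1-based, inclusive) everywhere in the
API; depth tracks are BED-like (0-based, half-open) and converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Genotype",
    "GenotypeObservation",
    "TrioPedigree",
    "SiteRecord",
    "DepthHistogram",
    "Cohort",
    "read_cohort",
    "read_ped",
    "read_ages",
    "read_known_sites",
    "write_vcf",
    "build_depth_histogram",
    "read_depth_track",
    "read_depth_histogram_tsv",
]

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")

SNV = "SNV"
INDEL = "indel"


class Genotype(IntEnum):
    """Bi-allelic genotype states; ``MISSING`` never passes any filter."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True)
class GenotypeObservation:
    """One sample's call at one site (GT, GQ, DP and allelic depths)."""

    sample_id: str
    gt: Genotype
    gq: int
    dp: int
    ad_ref: int
    ad_alt: int

    @property
    def ab(self) -> float | None:
        """Allele balance ad_alt/(ad_ref+ad_alt); None without informative reads."""
        total = self.ad_ref + self.ad_alt
        if total <= 0:
            return None
        return self.ad_alt / total


@dataclass(frozen=True)
class TrioPedigree:
    """One father-mother-child family, optionally with the father's age."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    father_age_at_birth: float | None = None

    def __post_init__(self) -> None:
        members = {self.child_id, self.father_id, self.mother_id}
        if len(members) != 3:
            raise ValueError(
                f"family {self.family_id}: child/father/mother ids must be distinct"
            )
        if self.father_age_at_birth is not None and self.father_age_at_birth <= 0:
            raise ValueError(f"family {self.family_id}: father age must be positive")

    @property
    def members(self) -> tuple[str, str, str]:
        return (self.child_id, self.father_id, self.mother_id)


@dataclass
class SiteRecord:
    """A bi-allelic variant site with one observation per cohort sample."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    known: bool = False
    site_stats: dict = field(default_factory=dict)
    observations: list[GenotypeObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos} ref == alt")

    @property
    def variant_type(self) -> str:
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    def observation(self, sample_id: str) -> GenotypeObservation:
        for obs in self.observations:
            if obs.sample_id == sample_id:
                return obs
        raise KeyError(sample_id)


class DepthHistogram:
    """Joint (child, father, mother) depth histogram over genomic positions.

    Stores the nonzero cells of the 3-way histogram as parallel arrays.
    """

    def __init__(
        self,
        d_child: np.ndarray,
        d_father: np.ndarray,
        d_mother: np.ndarray,
        counts: np.ndarray,
    ) -> None:
        self.d_child = np.asarray(d_child, dtype=np.int64)
        self.d_father = np.asarray(d_father, dtype=np.int64)
        self.d_mother = np.asarray(d_mother, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        if not (
            len(self.d_child) == len(self.d_father) == len(self.d_mother) == len(self.counts)
        ):
            raise ValueError("histogram arrays must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def total_positions(self) -> int:
        return int(self.counts.sum())

    def marginal(self, role: str) -> dict[int, int]:
        """Per-depth position counts for one trio member ('child'|'father'|'mother')."""
        depths = {"child": self.d_child, "father": self.d_father, "mother": self.d_mother}[role]
        out: dict[int, int] = {}
        for d, c in zip(depths.tolist(), self.counts.tolist()):
            out[d] = out.get(d, 0) + c
        return out

    @classmethod
    def from_positions(
        cls, d_child: np.ndarray, d_father: np.ndarray, d_mother: np.ndarray
    ) -> "DepthHistogram":
        triples = np.stack(
            [np.asarray(d_child), np.asarray(d_father), np.asarray(d_mother)], axis=1
        )
        cells, counts = np.unique(triples, axis=0, return_counts=True)
        return cls(cells[:, 0], cells[:, 1], cells[:, 2], counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_child": self.d_child,
                "d_father": self.d_father,
                "d_mother": self.d_mother,
                "count": self.counts,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DepthHistogram":
        return cls(
            df["d_child"].to_numpy(),
            df["d_father"].to_numpy(),
            df["d_mother"].to_numpy(),
            df["count"].to_numpy(),
        )


def read_depth_histogram_tsv(path: str | Path) -> DepthHistogram:
    """Read a precomputed 4-column (d_child, d_father, d_mother, count) TSV."""
    return DepthHistogram.from_frame(pd.read_csv(path, sep="\t"))


class Cohort:
    """A trio cohort: pedigrees plus per-site genotype arrays.

    Array layout: every per-sample quantity is an ``(n_sites, n_samples)``
    integer array in the fixed ``samples`` order.  ``gt`` uses the
    :class:`Genotype` codes (-1 missing, 0 hom-ref, 1 het, 2 hom-alt).
    """

    def __init__(
        self,
        pedigrees: Sequence[TrioPedigree],
        samples: Sequence[str],
        variants: pd.DataFrame,
        gt: np.ndarray,
        gq: np.ndarray,
        dp: np.ndarray,
        ad_ref: np.ndarray,
        ad_alt: np.ndarray,
        site_stats: dict | None = None,
        contigs: Mapping[str, int] | None = None,
    ) -> None:
        self.pedigrees = list(pedigrees)
        self.samples = list(samples)
        self.sample_index = {s: i for i, s in enumerate(self.samples)}
        self.variants = variants.reset_index(drop=True)
        self.gt = np.asarray(gt, dtype=np.int8)
        self.gq = np.asarray(gq, dtype=np.int32)
        self.dp = np.asarray(dp, dtype=np.int32)
        self.ad_ref = np.asarray(ad_ref, dtype=np.int32)
        self.ad_alt = np.asarray(ad_alt, dtype=np.int32)
        # site_stats holds optional per-site read-level summaries:
        #   srf/srr/saf/sar: int arrays (ref/alt read counts by strand)
        #   ref_pos/alt_pos: list (len n_sites) of int arrays of read offsets
        self.site_stats = site_stats or {}
        self.contigs = dict(contigs) if contigs else {}
        n, m = self.gt.shape
        if len(self.variants) != n or m != len(self.samples):
            raise ValueError("array shapes inconsistent with variants/samples")
        missing = [
            s
            for ped in self.pedigrees
            for s in ped.members
            if s not in self.sample_index
        ]
        if missing:
            raise ValueError(f"pedigree samples absent from cohort: {missing}")

    # ---- record-oriented access -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.variants)

    def family(self, family_id: str) -> TrioPedigree:
        for ped in self.pedigrees:
            if ped.family_id == family_id:
                return ped
        raise KeyError(family_id)

    def family_columns(self, ped: TrioPedigree) -> tuple[int, int, int]:
        return (
            self.sample_index[ped.child_id],
            self.sample_index[ped.father_id],
            self.sample_index[ped.mother_id],
        )

    def site(self, i: int) -> SiteRecord:
        row = self.variants.iloc[i]
        stats: dict = {}
        for key in ("srf", "srr", "saf", "sar"):
            if key in self.site_stats:
                stats[key] = int(self.site_stats[key][i])
        for key in ("ref_pos", "alt_pos"):
            if key in self.site_stats and self.site_stats[key][i] is not None:
                stats[key] = np.asarray(self.site_stats[key][i])
        obs = [
            GenotypeObservation(
                sample_id=s,
                gt=Genotype(int(self.gt[i, j])),
                gq=int(self.gq[i, j]),
                dp=int(self.dp[i, j]),
                ad_ref=int(self.ad_ref[i, j]),
                ad_alt=int(self.ad_alt[i, j]),
            )
            for j, s in enumerate(self.samples)
        ]
        return SiteRecord(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            known=bool(row["known"]),
            site_stats=stats,
            observations=obs,
        )

    def iter_sites(self) -> Iterator[SiteRecord]:
        for i in range(self.n_sites):
            yield self.site(i)


# ---- flat-file readers ---------------------------------------------------------


def read_ped(path: str | Path) -> list[TrioPedigree]:
    """Read a 6-column PED file; one trio (row with both parents set) per family."""
    trios: list[TrioPedigree] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, indiv, father, mother = line.split()[:4]
            if father == "0" or mother == "0":
                continue
            if fam in seen:
                raise ValueError(f"family id {fam!r} has more than one child row")
            seen.add(fam)
            trios.append(
                TrioPedigree(
                    family_id=fam, child_id=indiv, father_id=father, mother_id=mother
                )
            )
    return trios


def read_ages(path: str | Path) -> dict[str, float]:
    """Read a (family_id, father_age) TSV; a non-numeric second field is a header."""
    ages: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            try:
                age = float(parts[1])
            except ValueError:
                continue  # header
            ages[parts[0]] = age
    return ages


def read_known_sites(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a known-variants list from VCF or a chrom/pos/ref/alt TSV.

    Membership is keyed on exact (chrom, pos, ref, alt).
    """
    path = Path(path)
    keys: set[tuple[str, int, str, str]] = set()
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        with pysam.VariantFile(str(path)) as vf:
            for rec in vf:
                for alt in rec.alts or ():
                    keys.add((rec.chrom, rec.pos, rec.ref, alt))
        return keys
    with open(path) as fh:
        for line in fh:
            parts = line.strip().split("\t")
            if len(parts) < 4 or parts[0].startswith("#") or parts[0].lower() == "chrom":
                continue
            keys.add((parts[0], int(parts[1]), parts[2], parts[3]))
    return keys


def is_autosome(chrom: str) -> bool:
    return _AUTOSOME_RE.match(chrom) is not None


def read_cohort(
    vcf_path: str | Path,
    ped_path: str | Path,
    ages_path: str | Path | None = None,
    known_sites_path: str | Path | None = None,
    autosomes_only: bool = True,
    max_indel_len: int | None = None,
) -> tuple[Cohort, dict[str, int]]:
    """Load a multi-sample VCF plus pedigree/ages/known-sites into a Cohort.

    Returns ``(cohort, skipped)`` where ``skipped`` counts records dropped for
    each reason (multi-allelic, non-autosomal, symbolic alleles).  Missing
    per-sample FORMAT values yield ``Genotype.MISSING`` observations.  An
    unsorted VCF or a pedigree sample absent from the header is fatal.
    """
    trios = read_ped(ped_path)
    if ages_path is not None:
        ages = read_ages(ages_path)
        trios = [
            TrioPedigree(
                t.family_id,
                t.child_id,
                t.father_id,
                t.mother_id,
                father_age_at_birth=ages.get(t.family_id),
            )
            for t in trios
        ]
    known = read_known_sites(known_sites_path) if known_sites_path else set()

    skipped = {"multiallelic": 0, "non_autosome": 0, "symbolic": 0}
    rows = []
    gt_rows, gq_rows, dp_rows, adr_rows, ada_rows = [], [], [], [], []
    srf, srr, saf, sar, ref_pos, alt_pos = [], [], [], [], [], []
    has_strand = False
    has_pos = False

    with pysam.VariantFile(str(vcf_path)) as vf:
        header_samples = list(vf.header.samples)
        sample_set = set(header_samples)
        for t in trios:
            for s in t.members:
                if s not in sample_set:
                    raise ValueError(f"pedigree sample {s!r} absent from VCF header")
        samples = [s for t in trios for s in t.members]
        contigs = {name: c.length or 0 for name, c in vf.header.contigs.items()}

        last: tuple[str, int] | None = None
        seen_chroms: set[str] = set()
        for rec in vf:
            if last is not None and rec.chrom == last[0] and rec.pos < last[1]:
                raise ValueError(f"unsorted VCF at {rec.chrom}:{rec.pos}")
            if last is None or rec.chrom != last[0]:
                if rec.chrom in seen_chroms:
                    raise ValueError(f"unsorted VCF: chromosome {rec.chrom} interleaved")
                seen_chroms.add(rec.chrom)
            last = (rec.chrom, rec.pos)

            alts = rec.alts or ()
            if len(alts) != 1:
                skipped["multiallelic"] += 1
                continue
            alt = alts[0]
            if alt is None or alt.startswith("<") or "*" in alt:
                skipped["symbolic"] += 1
                continue
            if autosomes_only and not is_autosome(rec.chrom):
                skipped["non_autosome"] += 1
                continue

            gt_r, gq_r, dp_r, adr_r, ada_r = [], [], [], [], []
            for s in samples:
                sd = rec.samples[s]
                code, gq_v, dp_v, ad_v = _decode_sample(sd)
                gt_r.append(code)
                gq_r.append(gq_v)
                dp_r.append(dp_v)
                adr_r.append(ad_v[0])
                ada_r.append(ad_v[1])
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": alt,
                    "known": (rec.chrom, rec.pos, rec.ref, alt) in known,
                }
            )
            gt_rows.append(gt_r)
            gq_rows.append(gq_r)
            dp_rows.append(dp_r)
            adr_rows.append(adr_r)
            ada_rows.append(ada_r)

            info = rec.info
            if all(k in info for k in ("SRF", "SRR", "SAF", "SAR")):
                has_strand = True
                srf.append(int(info["SRF"]))
                srr.append(int(info["SRR"]))
                saf.append(int(info["SAF"]))
                sar.append(int(info["SAR"]))
            else:
                srf.append(0), srr.append(0), saf.append(0), sar.append(0)
            if "RPR" in info or "RPA" in info:
                has_pos = True
                ref_pos.append(np.asarray(info.get("RPR", ()), dtype=np.int64))
                alt_pos.append(np.asarray(info.get("RPA", ()), dtype=np.int64))
            else:
                ref_pos.append(None)
                alt_pos.append(None)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "known"])
    if max_indel_len is not None and len(variants):
        lengths = (variants["ref"].str.len() - variants["alt"].str.len()).abs()
        keep = (lengths < max_indel_len).to_numpy()
        skipped["long_indel"] = int((~keep).sum())
        variants = variants[keep]
        gt_rows = [r for r, k in zip(gt_rows, keep) if k]
        gq_rows = [r for r, k in zip(gq_rows, keep) if k]
        dp_rows = [r for r, k in zip(dp_rows, keep) if k]
        adr_rows = [r for r, k in zip(adr_rows, keep) if k]
        ada_rows = [r for r, k in zip(ada_rows, keep) if k]
        srf = [v for v, k in zip(srf, keep) if k]
        srr = [v for v, k in zip(srr, keep) if k]
        saf = [v for v, k in zip(saf, keep) if k]
        sar = [v for v, k in zip(sar, keep) if k]
        ref_pos = [v for v, k in zip(ref_pos, keep) if k]
        alt_pos = [v for v, k in zip(alt_pos, keep) if k]

    n = len(variants)
    m = len(samples)
    shape = (n, m)
    site_stats: dict = {}
    if has_strand:
        site_stats.update(
            srf=np.asarray(srf, dtype=np.int64),
            srr=np.asarray(srr, dtype=np.int64),
            saf=np.asarray(saf, dtype=np.int64),
            sar=np.asarray(sar, dtype=np.int64),
        )
    if has_pos:
        site_stats.update(ref_pos=ref_pos, alt_pos=alt_pos)

    cohort = Cohort(
        pedigrees=trios,
        samples=samples,
        variants=variants,
        gt=np.asarray(gt_rows, dtype=np.int8).reshape(shape),
        gq=np.asarray(gq_rows, dtype=np.int32).reshape(shape),
        dp=np.asarray(dp_rows, dtype=np.int32).reshape(shape),
        ad_ref=np.asarray(adr_rows, dtype=np.int32).reshape(shape),
        ad_alt=np.asarray(ada_rows, dtype=np.int32).reshape(shape),
        site_stats=site_stats,
        contigs=contigs,
    )
    return cohort, skipped


def _decode_sample(sd) -> tuple[int, int, int, tuple[int, int]]:
    gt = sd.get("GT")
    gq = sd.get("GQ")
    dp = sd.get("DP")
    ad = sd.get("AD")
    dp_v = int(dp) if dp is not None else 0
    ad_v = (
        (int(ad[0] or 0), int(ad[1] or 0))
        if ad is not None and len(ad) >= 2 and ad[0] is not None
        else (0, 0)
    )
    if gt is None or any(a is None for a in gt) or gq is None:
        return int(Genotype.MISSING), 0, dp_v, ad_v
    n_alt = sum(1 for a in gt if a == 1)
    code = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}[n_alt]
    return int(code), int(gq), dp_v, ad_v


# ---- VCF writing ---------------------------------------------------------------


def write_vcf(cohort: Cohort, path: str | Path, site_indices: Iterable[int] | None = None) -> None:
    """Write the cohort's sites back to an uncompressed VCF 4.2 file."""
    header = pysam.VariantHeader()
    contigs = dict(cohort.contigs)
    for chrom in cohort.variants["chrom"].unique():
        if chrom not in contigs or not contigs[chrom]:
            pos_max = int(cohort.variants.loc[cohort.variants["chrom"] == chrom, "pos"].max())
            contigs[chrom] = pos_max + 1000
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    has_strand = "srf" in cohort.site_stats
    has_pos = "ref_pos" in cohort.site_stats
    if has_strand:
        for key, desc in (
            ("SRF", "Ref reads, forward strand"),
            ("SRR", "Ref reads, reverse strand"),
            ("SAF", "Alt reads, forward strand"),
            ("SAR", "Alt reads, reverse strand"),
        ):
            header.info.add(key, 1, "Integer", desc)
    if has_pos:
        header.info.add("RPR", ".", "Integer", "Ref read offsets (subsample)")
        header.info.add("RPA", ".", "Integer", "Alt read offsets (subsample)")
    for s in cohort.samples:
        header.add_sample(s)

    gt_alleles = {
        int(Genotype.MISSING): (None, None),
        int(Genotype.HOM_REF): (0, 0),
        int(Genotype.HET): (0, 1),
        int(Genotype.HOM_ALT): (1, 1),
    }
    indices = range(cohort.n_sites) if site_indices is None else site_indices
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in indices:
            row = cohort.variants.iloc[i]
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            if has_strand:
                rec.info["SRF"] = int(cohort.site_stats["srf"][i])
                rec.info["SRR"] = int(cohort.site_stats["srr"][i])
                rec.info["SAF"] = int(cohort.site_stats["saf"][i])
                rec.info["SAR"] = int(cohort.site_stats["sar"][i])
            if has_pos and cohort.site_stats["ref_pos"][i] is not None:
                rpr = [int(v) for v in cohort.site_stats["ref_pos"][i]]
                rpa = [int(v) for v in cohort.site_stats["alt_pos"][i]]
                if rpr:
                    rec.info["RPR"] = rpr
                if rpa:
                    rec.info["RPA"] = rpa
            for j, s in enumerate(cohort.samples):
                code = int(cohort.gt[i, j])
                rec.samples[s]["GT"] = gt_alleles[code]
                if code != int(Genotype.MISSING):
                    rec.samples[s]["GQ"] = int(cohort.gq[i, j])
                rec.samples[s]["DP"] = int(cohort.dp[i, j])
                rec.samples[s]["AD"] = (int(cohort.ad_ref[i, j]), int(cohort.ad_alt[i, j]))
            out.write(rec)


# ---- depth tracks --------------------------------------------------------------


def read_depth_track(path: str | Path) -> pd.DataFrame:
    """Read a BED-like depth track (chrom, start, end, depth; 0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "depth"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "depth": np.int64},
    )
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping intervals in depth track {path} on {chrom}")
    return df


def _fill_depths(track: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Per-position depths over [start, end) with 0 for uncovered positions."""
    out = np.zeros(end - start, dtype=np.int64)
    sub = track[track["chrom"] == chrom]
    for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out[lo - start : hi - start] = d
    return out


def build_depth_histogram(
    tracks: Mapping[str, pd.DataFrame | str | Path],
    pedigree: TrioPedigree,
    regions: Sequence[tuple[str, int, int]],
    autosomes_only: bool = True,
) -> DepthHistogram:
    """Joint depth histogram for one family over BED regions (0-based half-open).

    ``tracks`` maps sample id to a depth-track DataFrame or file path.
    Positions absent from a track contribute depth 0; ``total_positions``
    equals the summed region length.
    """
    loaded = {
        s: (read_depth_track(t) if not isinstance(t, pd.DataFrame) else t)
        for s, t in tracks.items()
    }
    chunks_c, chunks_f, chunks_m = [], [], []
    for chrom, start, end in regions:
        if autosomes_only and not is_autosome(chrom):
            continue
        chunks_c.append(_fill_depths(loaded[pedigree.child_id], chrom, start, end))
        chunks_f.append(_fill_depths(loaded[pedigree.father_id], chrom, start, end))
        chunks_m.append(_fill_depths(loaded[pedigree.mother_id], chrom, start, end))
    if not chunks_c:
        return DepthHistogram(
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
    return DepthHistogram.from_positions(
        np.concatenate(chunks_c), np.concatenate(chunks_f), np.concatenate(chunks_m)
    )
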
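"""Input/output for reference panels, genotype call sets, read counts and imputed results.

External conventions:

* VCF 4.2 for the phased reference panel, array/truth genotypes and imputed
  output (FORMAT fields ``GT``, ``DS``, ``GP``).
* Counts TSV: tab-delimited with header ``chrom pos ref alt ref_count alt_count``.
* Variant subset TSV: tab-delimited with header ``chrom pos label``.

Coordinates are 1-based (VCF convention) on disk and in :class:`Site`;
matrix/site indices are 0-based everywhere else.  A withheld genotype is
encoded ``./.`` in VCF, the string ``NA`` in tables and the integer
:data:`NO_CALL` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

#: In-memory encoding of a withheld ("no-call") genotype.
NO_CALL = -1

COUNTS_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]


class PanelIOError(ValueError):
    """Malformed or inconsistent input data."""


class SiteMismatchError(PanelIOError):
    """Two site-indexed structures disagree on (chrom, pos, ref, alt)."""


@dataclass(frozen=True)
class Site:
    """A biallelic SNP: chromosome, 1-based position and its two alleles."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise PanelIOError(
                f"site {self.chrom}:{self.pos} has identical ref/alt alleles"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _check_sorted(sites: Sequence[Site]) -> None:
    for a, b in zip(sites, sites[1:]):
        if a.chrom == b.chrom and b.pos <= a.pos:
            raise PanelIOError(
                f"sites not strictly increasing: {a.chrom}:{a.pos} then {b.chrom}:{b.pos}"
            )


@dataclass
class HaplotypePanel:
    """Phased haplotype reference panel: K haplotypes x M biallelic sites.

    ``alleles[k, m]`` is 0 (ref) or 1 (alt) for haplotype ``k`` at site ``m``.
    The haplotypes are the copying templates of the imputation HMM.
    """

    sites: list[Site]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.uint8))
        if self.alleles.ndim != 2:
            raise PanelIOError("panel allele matrix must be 2-D (K x M)")
        K, M = self.alleles.shape
        if K < 2 or M < 1:
            raise PanelIOError(f"panel needs K >= 2 haplotypes and M >= 1 sites, got K={K}, M={M}")
        if M != len(self.sites):
            raise PanelIOError(f"allele matrix has {M} columns but {len(self.sites)} sites")
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelIOError("panel alleles must all be 0 or 1")
        _check_sorted(self.sites)

    @property
    def K(self) -> int:
        return self.alleles.shape[0]

    @property
    def M(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)

    def chrom_segments(self) -> list[tuple[int, int]]:
        """Half-open [start, stop) site-index ranges, one per chromosome."""
        segments: list[tuple[int, int]] = []
        start = 0
        for m in range(1, self.M):
            if self.sites[m].chrom != self.sites[m - 1].chrom:
                segments.append((start, m))
                start = m
        segments.append((start, self.M))
        return segments

    def allele_frequencies(self) -> np.ndarray:
        return self.alleles.mean(axis=0)


@dataclass
class GenotypeCalls:
    """Hard genotype calls for one sample: values in {0, 1, 2, NO_CALL}."""

    sites: list[Site]
    calls: np.ndarray
    sample: str = "sample"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites),):
            raise PanelIOError("calls length does not match number of sites")
        if not np.isin(self.calls, (0, 1, 2, NO_CALL)).all():
            raise PanelIOError("genotype calls must be in {0, 1, 2, NO_CALL}")


@dataclass
class VariantSet:
    """A labelled set of (chrom, pos) keys, e.g. ADME-gene variants."""

    members: frozenset[tuple[str, int]]
    label: str = "subset"

    def mask(self, sites: Sequence[Site]) -> np.ndarray:
        return np.asarray([s.key in self.members for s in sites], dtype=bool)

    def resolve(self, sites: Sequence[Site]) -> np.ndarray:
        """Boolean mask over ``sites``; error if any member is unresolvable."""
        keys = {s.key for s in sites}
        missing = self.members - keys
        if missing:
            example = sorted(missing)[0]
            raise PanelIOError(
                f"variant set '{self.label}' has {len(missing)} members absent from the "
                f"site list, e.g. {example[0]}:{example[1]}"
            )
        return self.mask(sites)


def check_aligned(a: Sequence[Site], b: Sequence[Site]) -> None:
    """Fail loudly unless two site lists agree on (chrom, pos, ref, alt)."""
    if len(a) != len(b):
        raise SiteMismatchError(f"site lists differ in length: {len(a)} vs {len(b)}")
    for i, (sa, sb) in enumerate(zip(a, b)):
        if (sa.chrom, sa.pos, sa.ref_allele, sa.alt_allele) != (
            sb.chrom,
            sb.pos,
            sb.ref_allele,
            sb.alt_allele,
        ):
            raise SiteMismatchError(
                f"site {i} mismatch: {sa.chrom}:{sa.pos} {sa.ref_allele}>{sa.alt_allele} "
                f"vs {sb.chrom}:{sb.pos} {sb.ref_allele}>{sb.alt_allele}"
            )


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _is_biallelic_snp(variant) -> bool:
    return (
        len(variant.REF) == 1
        and len(variant.ALT) == 1
        and len(variant.ALT[0]) == 1
        and variant.REF != variant.ALT[0]
    )


def load_reference_panel(path: str, strict: bool = True) -> HaplotypePanel:
    """Read a phased multi-sample VCF into a haplotype panel.

    Each of the N panel samples contributes two haplotypes (K = 2N).
    Multiallelic records, non-SNPs, and records with missing or unphased
    genotypes are rejected (``strict=True``) or silently skipped
    (``strict=False``).
    """
    vcf = VCF(path)
    sites: list[Site] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if not _is_biallelic_snp(variant):
            if strict:
                raise PanelIOError(
                    f"panel record {variant.CHROM}:{variant.POS} is not a biallelic SNP"
                )
            continue
        gts = variant.genotypes  # [allele1, allele2, phased] per sample
        ok = all(g[0] in (0, 1) and g[1] in (0, 1) and g[2] for g in gts)
        if not ok:
            if strict:
                raise PanelIOError(
                    f"panel record {variant.CHROM}:{variant.POS} has a missing or "
                    "unphased genotype"
                )
            continue
        sites.append(
            Site(variant.CHROM, variant.POS, variant.REF, variant.ALT[0], variant.ID)
        )
        rows.append(np.asarray([[g[0], g[1]] for g in gts], dtype=np.uint8).ravel())
    if not rows:
        raise PanelIOError(f"no usable biallelic phased SNP records in {path}")
    alleles = np.stack(rows, axis=1)  # (K, M)
    return HaplotypePanel(sites=sites, alleles=alleles)


def load_genotype_vcf(path: str) -> list[GenotypeCalls]:
    """Read hard genotype calls (array/truth VCF) for every sample."""
    vcf = VCF(path)
    samples = list(vcf.samples)
    sites: list[Site] = []
    cols: list[np.ndarray] = []
    for variant in vcf:
        if not _is_biallelic_snp(variant):
            raise PanelIOError(
                f"genotype record {variant.CHROM}:{variant.POS} is not a biallelic SNP"
            )
        sites.append(
            Site(variant.CHROM, variant.POS, variant.REF, variant.ALT[0], variant.ID)
        )
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            col[i] = NO_CALL if (a < 0 or b < 0) else a + b
        cols.append(col)
    matrix = np.stack(cols, axis=0)  # (M, n_samples)
    return [
        GenotypeCalls(sites=sites, calls=matrix[:, i], sample=name)
        for i, name in enumerate(samples)
    ]


def load_imputed_vcf(path: str) -> tuple[list[Site], np.ndarray, np.ndarray, np.ndarray]:
    """Read an imputed single-sample VCF back: (sites, hard calls, dosages, GP)."""
    vcf = VCF(path)
    if len(vcf.samples) != 1:
        raise PanelIOError(f"expected a single-sample imputed VCF, got {len(vcf.samples)}")
    sites: list[Site] = []
    calls: list[int] = []
    dosages: list[float] = []
    gps: list[np.ndarray] = []
    for variant in vcf:
        sites.append(
            Site(variant.CHROM, variant.POS, variant.REF, variant.ALT[0], variant.ID)
        )
        a, b = variant.genotypes[0][0], variant.genotypes[0][1]
        calls.append(NO_CALL if (a < 0 or b < 0) else a + b)
        dosages.append(float(variant.format("DS")[0][0]))
        gps.append(np.asarray(variant.format("GP")[0], dtype=float))
    return (
        sites,
        np.asarray(calls, dtype=np.int8),
        np.asarray(dosages, dtype=float),
        np.stack(gps, axis=0),
    )


# ---------------------------------------------------------------------------
# Counts and subsets
# ---------------------------------------------------------------------------

def load_counts(path: str, panel_sites: Sequence[Site]) -> np.ndarray:
    """Read a counts TSV and align it to the panel sites.

    Returns an (M, 2) integer array of (ref_count, alt_count) rows in panel
    site order.  Sites absent from the table get (0, 0) — absence means no
    coverage.  Rows whose (chrom, pos) is not a panel site are ignored; rows
    matching a panel site with different alleles raise
    :class:`SiteMismatchError` (no silent allele flipping).
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in COUNTS_COLUMNS if c not in table.columns]
    if missing:
        raise PanelIOError(f"counts table missing columns: {missing}")
    if len(table) and ((table["ref_count"] < 0).any() or (table["alt_count"] < 0).any()):
        raise PanelIOError("counts table contains negative counts")
    if table.duplicated(subset=["chrom", "pos"]).any():
        dup = table[table.duplicated(subset=["chrom", "pos"])].iloc[0]
        raise PanelIOError(f"duplicate counts row for {dup['chrom']}:{dup['pos']}")

    counts = np.zeros((len(panel_sites), 2), dtype=np.int64)
    index = {s.key: i for i, s in enumerate(panel_sites)}
    for row in table.itertuples(index=False):
        i = index.get((str(row.chrom), int(row.pos)))
        if i is None:
            continue
        site = panel_sites[i]
        if (row.ref, row.alt) != (site.ref_allele, site.alt_allele):
            raise SiteMismatchError(
                f"counts alleles {row.ref}>{row.alt} disagree with panel "
                f"{site.ref_allele}>{site.alt_allele} at {site.chrom}:{site.pos}"
            )
        counts[i, 0] = int(row.ref_count)
        counts[i, 1] = int(row.alt_count)
    return counts


def write_counts_tsv(sites: Sequence[Site], counts: np.ndarray, path: str) -> None:
    counts = np.asarray(counts, dtype=np.int64)
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref_allele for s in sites],
            "alt": [s.alt_allele for s in sites],
            "ref_count": counts[:, 0],
            "alt_count": counts[:, 1],
        }
    ).to_csv(path, sep="\t", index=False)


def load_variant_subset(path: str) -> VariantSet:
    """Read a 'chrom pos label' TSV into a single variant set.

    The label of the set is the (unique) label column value; mixed labels
    are concatenated with '+'.
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "pos", "label"):
        if col not in table.columns:
            raise PanelIOError(f"variant subset table missing column '{col}'")
    keys = list(zip(table["chrom"].astype(str), table["pos"].astype(int)))
    if len(set(keys)) != len(keys):
        raise PanelIOError("variant subset table has duplicate (chrom, pos) keys")
    labels = sorted(set(table["label"].astype(str)))
    return VariantSet(members=frozenset(keys), label="+".join(labels) or "subset")


def write_variant_subset(subset: VariantSet, path: str) -> None:
    rows = sorted(subset.members)
    pd.DataFrame(
        {"chrom": [c for c, _ in rows], "pos": [p for _, p in rows], "label": subset.label}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF writing (plain-text VCF 4.2; read back with htslib-based tooling)
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=lowpasskit
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_IMPUTED_FORMAT_HEADER = (
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed alternate allele dosage">\n'
    '##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior probabilities">\n'
)


def _contig_lines(sites: Sequence[Site]) -> str:
    chroms: list[str] = []
    for s in sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    return "".join(f"##contig=<ID={c}>\n" for c in chroms)


def _site_cols(site: Site) -> str:
    vid = site.id if site.id else "."
    return (
        f"{site.chrom}\t{site.pos}\t{vid}\t{site.ref_allele}\t{site.alt_allele}\t.\t.\t."
    )


def write_panel_vcf(panel: HaplotypePanel, path: str, sample_prefix: str = "panel") -> None:
    """Write the panel as a phased multi-sample VCF (haplotypes 2k, 2k+1 pair up)."""
    n = panel.K // 2
    if panel.K != 2 * n:
        raise PanelIOError("panel K must be even to serialize as diploid VCF samples")
    names = [f"{sample_prefix}{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(panel.sites))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n"
        )
        for m, site in enumerate(panel.sites):
            gts = "\t".join(
                f"{panel.alleles[2 * i, m]}|{panel.alleles[2 * i + 1, m]}" for i in range(n)
            )
            fh.write(f"{_site_cols(site)}\tGT\t{gts}\n")


def write_genotype_vcf(calls_per_sample: Sequence[GenotypeCalls], path: str) -> None:
    """Write unphased hard calls (truth/array style) for one or more samples."""
    if not calls_per_sample:
        raise PanelIOError("no samples to write")
    sites = calls_per_sample[0].sites
    for gc in calls_per_sample[1:]:
        check_aligned(sites, gc.sites)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", NO_CALL: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(sites))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gc.sample for gc in calls_per_sample)
            + "\n"
        )
        for m, site in enumerate(sites):
            gts = "\t".join(gt_map[int(gc.calls[m])] for gc in calls_per_sample)
            fh.write(f"{_site_cols(site)}\tGT\t{gts}\n")


def write_imputed_vcf(result, sites: Sequence[Site], path: str, sample: str = "imputed") -> None:
    """Serialize an imputation result: GT (hard call), DS (dosage), GP (posterior).

    The GP triplet must already be normalized; a row whose sum strays from 1
    by more than 1e-6 indicates an internal inconsistency and is refused.
    """
    posteriors = np.asarray(result.posteriors, dtype=float)
    if posteriors.shape != (len(sites), 3):
        raise PanelIOError("imputation result is not aligned to the site list")
    sums = posteriors.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-6:
        m = int(np.abs(sums - 1.0).argmax())
        raise PanelIOError(
            f"posterior triplet at site index {m} sums to {sums[m]:.8f}, not 1"
        )
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", NO_CALL: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_IMPUTED_FORMAT_HEADER)
        fh.write(_contig_lines(sites))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for m, site in enumerate(sites):
            gt = gt_map[int(result.hard_calls[m])]
            ds = f"{result.dosages[m]:.3f}"
            gp = ",".join(f"{p:.4f}" for p in posteriors[m])
            fh.write(f"{_site_cols(site)}\tGT:DS:GP\t{gt}:{ds}:{gp}\n")
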
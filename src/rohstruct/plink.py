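"""PLINK-format genotype I/O and the in-memory genotype data model.

The canonical container is :class:`GenotypeDataset`: a samples x variants
matrix of diploid dosages (copies of ``allele_b``) in ``{0, 1, 2, MISSING}``
together with a physical map and per-sample metadata.  Only the 29 bovine
autosomes are modelled; rows with any other chromosome code are dropped on
read (with a logged count).

Supported formats are PLINK PED/MAP text and PLINK 1 binary BED/BIM/FAM
(SNP-major, magic bytes ``6C 1B 01``).  Sample metadata that FAM cannot
carry (subgroup, herd, sire, birth year, panel density) travels in a sidecar
TSV ``<prefix>.meta.tsv``; the allele orientation that PED cannot carry
travels in ``<prefix>.alleles.tsv``.  Both sidecars are optional on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call in the int8 dosage matrix.
MISSING: int = -1

#: Autosome indices modelled throughout (Bos taurus has 29 autosomes).
AUTOSOMES = tuple(range(1, 30))

SAMPLE_META_COLUMNS = [
    "sample_id", "subgroup", "herd_id", "sire_id", "birth_year", "panel_density",
]
VARIANT_COLUMNS = ["variant_id", "chrom", "pos_bp", "allele_a", "allele_b"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PlinkFormatError(ValueError):
    """Raised when a PLINK file violates the format contract."""


@dataclass
class GenotypeDataset:
    """Diploid SNP genotypes with physical map and sample metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        One row per sample, columns ``sample_id, subgroup, herd_id, sire_id,
        birth_year, panel_density``.  ``sample_id`` is unique.
    variants : pandas.DataFrame
        One row per variant, columns ``variant_id, chrom, pos_bp, allele_a,
        allele_b``; sorted by (chrom, pos_bp), positions 1-based.
    calls : numpy.ndarray of int8, shape (n_samples, n_variants)
        Dosage of ``allele_b`` in {0, 1, 2} or :data:`MISSING`.
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        """Raise ``ValueError`` if any container invariant is violated."""
        if self.calls.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({self.n_samples}, {self.n_variants})"
            )
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id")
        chrom = self.variants["chrom"].to_numpy()
        if len(chrom) and not np.isin(chrom, AUTOSOMES).all():
            raise ValueError("non-autosomal chromosome code in variants")
        pos = self.variants["pos_bp"].to_numpy()
        if len(pos) and pos.min() < 1:
            raise ValueError("pos_bp must be 1-based (>= 1)")
        # sorted by chrom then position; equal positions allowed (input order)
        order = np.lexsort((np.arange(len(chrom)), pos, chrom))
        if not np.array_equal(order, np.arange(len(chrom))):
            raise ValueError("variants not sorted by (chrom, pos_bp)")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,MISSING}")

    # -- subsetting -------------------------------------------------------
    def take_samples(self, index) -> "GenotypeDataset":
        """Positional subset of samples (order preserved)."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.iloc[index], self.variants, self.calls[index]
        )

    def take_variants(self, index) -> "GenotypeDataset":
        """Positional subset of variants (order preserved)."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples, self.variants.iloc[index], self.calls[:, index]
        )

    def subset_by_sample_id(self, ids) -> "GenotypeDataset":
        pos = self.samples.reset_index().set_index("sample_id").loc[list(ids), "index"]
        return self.take_samples(pos.to_numpy())

    def subset_by_variant_id(self, ids) -> "GenotypeDataset":
        pos = self.variants.reset_index().set_index("variant_id").loc[list(ids), "index"]
        return self.take_variants(np.sort(pos.to_numpy()))

    def equals(self, other: "GenotypeDataset") -> bool:
        """Strict equality of samples, variants and calls."""
        return (
            self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and self.variants.reset_index(drop=True).equals(other.variants.reset_index(drop=True))
            and np.array_equal(self.calls, other.calls)
        )

    def flip_alleles(self, variant_index) -> "GenotypeDataset":
        """Swap allele_a/allele_b at the given variants; dosage d -> 2 - d."""
        variants = self.variants.copy()
        calls = self.calls.copy()
        for j in np.atleast_1d(variant_index):
            a, b = variants.loc[j, ["allele_a", "allele_b"]]
            variants.loc[j, "allele_a"], variants.loc[j, "allele_b"] = b, a
            col = calls[:, j]
            obs = col != MISSING
            col[obs] = 2 - col[obs]
        return GenotypeDataset(self.samples, variants, calls)


def _default_sample_meta(sample_ids, herd_ids=None) -> pd.DataFrame:
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "subgroup": [pd.NA] * n,
        "herd_id": list(herd_ids) if herd_ids is not None else [pd.NA] * n,
        "sire_id": [pd.NA] * n,
        "birth_year": pd.array([pd.NA] * n, dtype="Int64"),
        "panel_density": pd.array([pd.NA] * n, dtype="Int64"),
    })


def _merge_sidecar_meta(samples: pd.DataFrame, meta_path: Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "subgroup": str,
                                                   "herd_id": str, "sire_id": str})
    for col in ("birth_year", "panel_density"):
        if col in meta:
            meta[col] = meta[col].astype("Int64")
    merged = samples[["sample_id"]].merge(meta, on="sample_id", how="left")
    for col in SAMPLE_META_COLUMNS:
        if col not in merged:
            merged[col] = pd.NA
        elif col in ("subgroup", "herd_id", "sire_id"):
            merged[col] = merged[col].astype(object).where(merged[col].notna(), pd.NA)
    return merged[SAMPLE_META_COLUMNS]


def _finalise_dataset(samples, variants, calls, prefix: Path | None) -> GenotypeDataset:
    """Sort variants by (chrom, pos), attach sidecar metadata if present."""
    variants = variants.reset_index(drop=True)
    order = np.lexsort((
        np.arange(len(variants)),
        variants["pos_bp"].to_numpy(),
        variants["chrom"].to_numpy(),
    ))
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    if prefix is not None:
        meta_path = Path(str(prefix) + ".meta.tsv")
        if meta_path.exists():
            samples = _merge_sidecar_meta(samples, meta_path)
    ds = GenotypeDataset(samples, variants, calls)
    ds.validate()
    return ds


def _parse_map(map_path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a MAP/BIM-like table; return (autosomal rows, keep mask)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (4, 6):
                raise PlinkFormatError(
                    f"{map_path}: line {lineno}: expected 4 (MAP) or 6 (BIM) "
                    f"columns, found {len(parts)}"
                )
            rows.append(parts)
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS), np.zeros(0, dtype=bool)
    ncol = len(rows[0])
    chroms = []
    keep = np.zeros(len(rows), dtype=bool)
    for i, parts in enumerate(rows):
        try:
            c = int(parts[0])
        except ValueError:
            c = -1
        chroms.append(c)
        keep[i] = c in AUTOSOMES
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluded %d non-autosomal variant(s) from %s", n_dropped, map_path)
    kept = [rows[i] for i in np.flatnonzero(keep)]
    variants = pd.DataFrame({
        "variant_id": [r[1] for r in kept],
        "chrom": [int(r[0]) for r in kept],
        "pos_bp": [int(r[3]) for r in kept],
        "allele_a": [r[4] if ncol == 6 else "0" for r in kept],
        "allele_b": [r[5] if ncol == 6 else "0" for r in kept],
    })
    return variants, keep


def read_plink_text(ped_path, map_path, alleles_path=None) -> GenotypeDataset:
    """Read PED/MAP text files into a :class:`GenotypeDataset`.

    Dosage counts ``allele_b``.  Orientation comes from, in order of
    preference: an explicit ``alleles_path`` TSV (variant_id, allele_a,
    allele_b), an auto-detected ``<ped stem>.alleles.tsv`` sidecar, or the
    order of first appearance of the two alleles in the PED column.
    ``0 0`` pairs decode to :data:`MISSING`; non-autosomal map rows are
    excluded with a logged count.
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    variants, keep = _parse_map(map_path)
    n_map = len(keep)
    kept_idx = np.flatnonzero(keep)

    sample_ids, fam_ids, geno_rows = [], [], []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_map:
                raise PlinkFormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_map} fields "
                    f"(6 + 2 x {n_map} variants), found {len(parts)}"
                )
            fam_ids.append(parts[0])
            sample_ids.append(parts[1])
            alleles = parts[6:]
            geno_rows.append([(alleles[2 * j], alleles[2 * j + 1]) for j in kept_idx])

    n_samples, n_var = len(sample_ids), len(variants)
    calls = np.full((n_samples, n_var), MISSING, dtype=np.int8)

    # allele orientation per variant
    ref = None
    if alleles_path is None:
        candidate = ped_path.with_suffix("")
        sidecar = Path(str(candidate) + ".alleles.tsv")
        if sidecar.exists():
            alleles_path = sidecar
    if alleles_path is not None:
        ref = pd.read_csv(alleles_path, sep="\t", dtype=str).set_index("variant_id")

    allele_a = np.empty(n_var, dtype=object)
    allele_b = np.empty(n_var, dtype=object)
    for j in range(n_var):
        vid = variants.iloc[j]["variant_id"]
        if ref is not None and vid in ref.index:
            a, b = ref.loc[vid, "allele_a"], ref.loc[vid, "allele_b"]
        else:
            a = b = None
            for i in range(n_samples):
                for al in geno_rows[i][j]:
                    if al == "0":
                        continue
                    if a is None:
                        a = al
                    elif al != a and b is None:
                        b = al
                if b is not None:
                    break
            a = a if a is not None else "0"
            b = b if b is not None else "0"
        allele_a[j], allele_b[j] = a, b
        for i in range(n_samples):
            a1, a2 = geno_rows[i][j]
            if a1 == "0" or a2 == "0":
                continue
            d = 0
            for al in (a1, a2):
                if al == b:
                    d += 1
                elif al != a:
                    raise PlinkFormatError(
                        f"{ped_path}: sample {sample_ids[i]}, variant {vid}: "
                        f"unexpected allele {al!r} (known: {a!r}/{b!r})"
                    )
            calls[i, j] = d

    variants = variants.assign(allele_a=allele_a, allele_b=allele_b)
    samples = _default_sample_meta(sample_ids, herd_ids=fam_ids)
    return _finalise_dataset(samples, variants, calls, ped_path.with_suffix(""))


def read_plink_binary(prefix) -> GenotypeDataset:
    """Read PLINK 1 binary ``prefix.bed/.bim/.fam`` (SNP-major).

    2-bit codes per call: ``00`` hom allele_a, ``01`` missing, ``10`` het,
    ``11`` hom allele_b; dosage counts allele_b.
    """
    prefix = Path(prefix)
    bed, bim, fam = (Path(str(prefix) + ext) for ext in (".bed", ".bim", ".fam"))
    variants, keep = _parse_map(bim)

    fam_rows = [line.split() for line in open(fam) if line.split()]
    sample_ids = [r[1] for r in fam_rows]
    fam_ids = [r[0] for r in fam_rows]
    n_samples, n_map = len(sample_ids), len(keep)

    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes (expected 6C 1B 01 SNP-major)")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    bytes_per_snp = (n_samples + 3) // 4
    if len(body) != bytes_per_snp * n_map:
        raise PlinkFormatError(
            f"{bed}: size implies {len(body) / max(bytes_per_snp, 1):.1f} variants "
            f"for {n_samples} samples, but .bim lists {n_map}"
        )
    packed = body.reshape(n_map, bytes_per_snp)
    # expand 2-bit fields, sample i in bits (2i mod 8) of byte i//4
    codes = np.empty((n_map, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    codes = codes[:, :n_samples]
    lut = np.array([0, MISSING, 1, 2], dtype=np.int8)  # 00,01,10,11
    calls = lut[codes].T[:, keep]

    samples = _default_sample_meta(sample_ids, herd_ids=fam_ids)
    return _finalise_dataset(samples, variants.reset_index(drop=True), calls, prefix)


def _write_sidecar_meta(dataset: GenotypeDataset, prefix: Path) -> None:
    dataset.samples[SAMPLE_META_COLUMNS].to_csv(
        str(prefix) + ".meta.tsv", sep="\t", index=False
    )


def write_plink(dataset: GenotypeDataset, prefix, format: str = "binary") -> None:
    """Write ``dataset`` as PED/MAP (``format="text"``) or BED/BIM/FAM.

    Both formats also emit ``<prefix>.meta.tsv`` with the sample metadata;
    the text format additionally emits ``<prefix>.alleles.tsv`` so that the
    dosage orientation survives a round trip.
    """
    dataset.validate()
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = dataset.variants
    s = dataset.samples
    fam_id = s["herd_id"].fillna("0").astype(str)

    if format == "text":
        with open(str(prefix) + ".map", "w") as fh:
            for row in v.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.variant_id}\t0\t{row.pos_bp}\n")
        pair = {0: "{a} {a}", 1: "{a} {b}", 2: "{b} {b}", MISSING: "0 0"}
        with open(str(prefix) + ".ped", "w") as fh:
            for i in range(dataset.n_samples):
                fields = [fam_id.iloc[i], str(s["sample_id"].iloc[i]), "0", "0", "0", "-9"]
                row = dataset.calls[i]
                for j in range(dataset.n_variants):
                    fields.append(pair[int(row[j])].format(
                        a=v["allele_a"].iloc[j], b=v["allele_b"].iloc[j]))
                fh.write(" ".join(fields) + "\n")
        v[["variant_id", "allele_a", "allele_b"]].to_csv(
            str(prefix) + ".alleles.tsv", sep="\t", index=False)
    elif format == "binary":
        with open(str(prefix) + ".bim", "w") as fh:
            for row in v.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.variant_id}\t0\t{row.pos_bp}"
                         f"\t{row.allele_a}\t{row.allele_b}\n")
        with open(str(prefix) + ".fam", "w") as fh:
            for i in range(dataset.n_samples):
                fh.write(f"{fam_id.iloc[i]} {s['sample_id'].iloc[i]} 0 0 0 -9\n")
        n = dataset.n_samples
        bytes_per_snp = (n + 3) // 4
        enc = np.array([0b00, 0b10, 0b11], dtype=np.uint8)
        codes = np.full((dataset.n_variants, bytes_per_snp * 4), 0b01, dtype=np.uint8)
        calls_t = dataset.calls.T
        obs = calls_t != MISSING
        block = np.full_like(codes[:, :n], 0b01)
        block[obs] = enc[calls_t[obs]]
        codes[:, :n] = block
        codes[:, n:] = 0b00  # padding bits are zero per the format
        packed = np.zeros((dataset.n_variants, bytes_per_snp), dtype=np.uint8)
        for k in range(4):
            packed |= codes[:, k::4] << (2 * k)
        with open(str(prefix) + ".bed", "wb") as fh:
            fh.write(_BED_MAGIC)
            fh.write(packed.tobytes())
    else:
        raise ValueError(f"unknown format {format!r} (expected 'text' or 'binary')")
    _write_sidecar_meta(dataset, prefix)
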
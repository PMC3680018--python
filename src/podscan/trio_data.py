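"""Trio SNP-array data model and I/O.

A trio dataset holds, for every SNP, the genotype call, B-allele frequency
(BAF) and log R ratio (LRR) of father, mother and child, sorted by genomic
position and indexed by chromosome arm.  Coordinates are 1-based inclusive
internally; BED output uses the 0-based half-open convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes
AA, AB, BB, NC = 0, 1, 2, 3
GT_LABELS = np.array(["AA", "AB", "BB", "NC"])
_GT_CODE = {"AA": AA, "AB": AB, "BA": AB, "BB": BB, "NC": NC}

MEMBERS = ("father", "mother", "child")
_PREFIX = {"father": "F", "mother": "M", "child": "C"}

AUTOSOMES = tuple(str(i) for i in range(1, 23))


def mirrored_baf(baf, center):
    """Reflect BAF values about the nonhomozygous band center.

    mBAF = center + |baf - center|, so the two arms of a split
    heterozygous band fold onto one side.  Idempotent.
    """
    baf = np.asarray(baf, dtype=float)
    return center + np.abs(baf - center)


@dataclass
class Region:
    """A detected abnormal interval on one chromosome arm."""

    chrom: str
    arm: str
    start_idx: int          # global SNP index, inclusive
    end_idx: int            # global SNP index, inclusive
    start_pos: int = 0      # base pairs, 1-based inclusive
    end_pos: int = 0
    detector: str = "POD"   # POD | PODhd | PODmi1 | PODcr
    parent: str = "undetermined"  # father | mother | both | undetermined
    abn_type: str = "NA"    # AMP | DEL | HD | UPhD | UPiD | NA
    inheritance: str = ""   # INH | INH-CN | ""
    n_snps: int = 0
    n_informative: int = 0
    med_mbaf: dict = field(default_factory=dict)   # per member, baseline-subtracted
    med_lrr: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.end_idx < self.start_idx:
            raise ValueError("region end before start")
        if self.n_snps == 0:
            self.n_snps = self.end_idx - self.start_idx + 1

    @property
    def span(self) -> tuple[int, int]:
        return self.start_idx, self.end_idx

    def overlaps(self, other: "Region") -> bool:
        return self.start_idx <= other.end_idx and other.start_idx <= self.end_idx

    def parent_code(self) -> str:
        code = {"father": "F", "mother": "M", "both": "B", "undetermined": "U"}[self.parent]
        # when no abnormality type was assigned, designate the parental
        # contributor rather than an origin call
        if self.abn_type == "NA" and code in ("F", "M"):
            return f"{code}(C)"
        return code


class TrioDataset:
    """SNP records for one parent-child trio, sorted and arm-indexed.

    Parameters
    ----------
    df : DataFrame with columns name, chrom, pos, and per-member
        ``{f,m,c}_gt`` (int8 codes), ``{f,m,c}_baf``, ``{f,m,c}_lrr``.
    arms : mapping arm label (e.g. ``"5p"``) -> (start, end) half-open
        global index range.  Arms partition the rows.
    """

    def __init__(self, df: pd.DataFrame, arms: Mapping[str, tuple[int, int]]):
        self.df = df.reset_index(drop=True)
        self.arms = dict(arms)
        n = sum(e - s for s, e in self.arms.values())
        if n != len(self.df):
            raise ValueError(f"arm index covers {n} SNPs, dataset has {len(self.df)}")
        self.pos = self.df["pos"].to_numpy()
        self.chrom = self.df["chrom"].to_numpy()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.df)

    def gt(self, member: str) -> np.ndarray:
        return self.df[f"{_PREFIX[member].lower()}_gt"].to_numpy()

    def baf(self, member: str) -> np.ndarray:
        return self.df[f"{_PREFIX[member].lower()}_baf"].to_numpy()

    def lrr(self, member: str) -> np.ndarray:
        return self.df[f"{_PREFIX[member].lower()}_lrr"].to_numpy()

    def arm_of(self, idx: int) -> str:
        for arm, (s, e) in self.arms.items():
            if s <= idx < e:
                return arm
        raise IndexError(idx)

    def arm_slice(self, arm: str) -> slice:
        s, e = self.arms[arm]
        return slice(s, e)

    def arms_of_chrom(self, chrom: str) -> list[str]:
        return [a for a in self.arms if a.rstrip("pq") == chrom]


# ---------------------------------------------------------------------------
# input
# ---------------------------------------------------------------------------

_REQUIRED = ["Name", "Chr", "Position"] + [
    f"{p}.{f}" for p in "FMC" for f in ("GType", "BAF", "LRR")
]


def load_centromeres(build: str = "hg19") -> pd.DataFrame:
    """Bundled centromere table: chrom, p_end, q_start (base pairs)."""
    with resources.files("podscan.data").joinpath(f"centromeres_{build}.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def build_arm_index(chrom: np.ndarray, pos: np.ndarray, centromeres: pd.DataFrame) -> dict:
    """Map (sorted) SNP coordinates to contiguous chromosome-arm index ranges."""
    cen = centromeres.set_index("chrom")
    arms: dict[str, tuple[int, int]] = {}
    i = 0
    n = len(chrom)
    while i < n:
        c = chrom[i]
        j = i
        while j < n and chrom[j] == c:
            j += 1
        p_end = int(cen.loc[c, "p_end"])
        split = i + int(np.searchsorted(pos[i:j], p_end, side="right"))
        if split > i:
            arms[f"{c}p"] = (i, split)
        if j > split:
            arms[f"{c}q"] = (split, j)
        i = j
    return arms


def read_trio_table(path, centromeres: pd.DataFrame | None = None,
                    build: str = "hg19") -> TrioDataset:
    """Read a tab-delimited trio table (GenomeStudio final-report style).

    Expected header: ``Name Chr Position F.GType F.BAF F.LRR M.GType M.BAF
    M.LRR C.GType C.BAF C.LRR``.  Rows are sorted by (chrom, pos), BAF is
    clipped to [0, 1], unrecognised genotype strings become NC, and
    non-autosomal rows are dropped with a logged warning.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    if raw.empty:
        raise ValueError(f"{path}: empty trio table")
    missing = [c for c in _REQUIRED if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    raw["Chr"] = raw["Chr"].str.removeprefix("chr")
    n0 = len(raw)
    raw = raw[raw["Chr"].isin(AUTOSOMES)]
    if len(raw) < n0:
        logger.warning("dropped %d non-autosomal SNPs", n0 - len(raw))
    if raw.empty:
        raise ValueError(f"{path}: no autosomal SNPs")

    raw["_chrnum"] = raw["Chr"].astype(int)
    raw = raw.sort_values(["_chrnum", "Position"], kind="mergesort")

    df = pd.DataFrame({
        "name": raw["Name"].to_numpy(),
        "chrom": raw["Chr"].to_numpy(),
        "pos": raw["Position"].to_numpy(np.int64),
    })
    for p in "FMC":
        col = p.lower()
        gts = raw[f"{p}.GType"].astype(str).str.upper()
        df[f"{col}_gt"] = gts.map(_GT_CODE).fillna(NC).astype(np.int8).to_numpy()
        df[f"{col}_baf"] = np.clip(raw[f"{p}.BAF"].to_numpy(float), 0.0, 1.0)
        df[f"{col}_lrr"] = raw[f"{p}.LRR"].to_numpy(float)

    if centromeres is None:
        centromeres = load_centromeres(build)
    arms = build_arm_index(df["chrom"].to_numpy(), df["pos"].to_numpy(), centromeres)
    return TrioDataset(df, arms)


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

REGION_COLUMNS = [
    "chrom", "start_pos", "end_pos", "detector", "parent", "abn_type",
    "inheritance", "n_snps", "n_informative",
    "F_mBAF", "M_mBAF", "C_mBAF", "F_LRR", "M_LRR", "C_LRR",
]


def regions_to_frame(regions: Sequence[Region]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({
            "chrom": r.chrom,
            "start_pos": r.start_pos,
            "end_pos": r.end_pos,
            "detector": r.detector,
            "parent": r.parent,
            "abn_type": r.abn_type,
            "inheritance": r.inheritance or ".",
            "n_snps": r.n_snps,
            "n_informative": r.n_informative,
            **{f"{_PREFIX[m]}_mBAF": round(r.med_mbaf.get(m, float("nan")), 4)
               for m in MEMBERS},
            **{f"{_PREFIX[m]}_LRR": round(r.med_lrr.get(m, float("nan")), 4)
               for m in MEMBERS},
        })
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_outputs(regions: Sequence[Region], out_dir, prefix: str = "trio",
                  params_table: pd.DataFrame | None = None,
                  log_lines: Iterable[str] = ()) -> dict:
    """Write the region table, BED file and optional parameter/log files.

    Returns a dict of written paths.  BED names are ``abnType:parent`` with
    the ``F(C)``/``M(C)`` contributor designation for untyped regions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    table = out_dir / f"{prefix}_regions.tsv"
    regions_to_frame(regions).to_csv(table, sep="\t", index=False)
    paths["table"] = table

    bed = out_dir / f"{prefix}_regions.bed"
    with open(bed, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_pos - 1}\t{r.end_pos}\t"
                     f"{r.abn_type}:{r.parent_code()}\n")
    paths["bed"] = bed

    if params_table is not None:
        ppath = out_dir / f"{prefix}_parameters.tsv"
        params_table.to_csv(ppath, sep="\t", index=False)
        paths["params"] = ppath
    log_lines = list(log_lines)
    if log_lines:
        lpath = out_dir / f"{prefix}.log"
        lpath.write_text("\n".join(log_lines) + "\n")
        paths["log"] = lpath
    return paths


def read_region_table(path) -> pd.DataFrame:
    # "NA" is a legitimate abnormality-type value, not a missing marker
    return pd.read_csv(path, sep="\t", dtype={"chrom": str},
                       keep_default_na=False, na_values=[""])
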
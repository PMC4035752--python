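"""Core site/call/validation data structures and the flat-file formats that carry them.

The unit of calling and validation is a :class:`Site` — a single-nucleotide
substitution keyed exactly on (chrom, pos, ref, alt). A :class:`CallDataset`
aligns, per site, the binary detection status of each caller, the validation
label (1 = confirmed somatic), optional genomic features, and optional
per-caller extras (quality score, filter flags).

Datasets are always union-ascertained: every site was detected by at least
one caller, and only successfully validated sites are retained when labels
are attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

#: The 12 ordered ref->alt substitution types, in double-lexicographic order.
SUBSTITUTION_TYPES = tuple(f"{r}>{a}" for r in BASES for a in BASES if r != a)

#: Numeric genomic feature columns, in canonical order.
NUMERIC_FEATURES = ("depth_tumor", "depth_normal", "vaf_tumor", "vaf_normal")


class DataError(ValueError):
    """A dataset violates one of its structural invariants."""


def normalize_chrom(chrom: str) -> str:
    """Strip an optional 'chr' prefix so mixed chromosome dialects compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True, order=True)
class Site:
    """A single-nucleotide somatic variant candidate.

    Two sites are identical iff all four fields match; different alt
    alleles at one position are distinct mutations.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.pos < 1:
            raise DataError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise DataError(f"alleles must be single bases A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise DataError(f"ref and alt must differ at {self.chrom}:{self.pos}")

    @property
    def substitution(self) -> str:
        return f"{self.ref}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenomicFeatures:
    """Per-site descriptors: read depths, variant allele fractions, substitution.

    ``None`` marks a missing value; missing numeric features are imputed
    downstream by the stacking module, never here.
    """

    depth_tumor: int | None = None
    depth_normal: int | None = None
    vaf_tumor: float | None = None
    vaf_normal: float | None = None
    substitution: str | None = None

    def __post_init__(self) -> None:
        for name in ("depth_tumor", "depth_normal"):
            v = getattr(self, name)
            if v is not None and (v < 0 or int(v) != v):
                raise DataError(f"{name} must be a non-negative integer, got {v!r}")
        for name in ("vaf_tumor", "vaf_normal"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1], got {v!r}")
        if self.substitution is not None and self.substitution not in SUBSTITUTION_TYPES:
            raise DataError(f"unknown substitution type {self.substitution!r}")


def _chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


def _site_sort_key(s: Site) -> tuple:
    return (*_chrom_sort_key(s.chrom), s.pos, s.ref, s.alt)


@dataclass
class CallDataset:
    """Aligned per-site caller calls, validation labels, and features.

    Attributes
    ----------
    sites:
        Ordered, duplicate-free list of n sites.
    caller_names:
        The K caller identifiers, fixing column order of ``calls``.
    calls:
        n x K binary matrix; ``calls[i, k] == 1`` iff caller k detected site i.
        Every row has at least one 1 (union ascertainment).
    labels:
        Optional length-n 0/1 vector, 1 = validated somatic mutation.
    features:
        Optional DataFrame with columns ``depth_tumor, depth_normal,
        vaf_tumor, vaf_normal, substitution`` aligned to ``sites``
        positionally; NaN marks missing numeric values.
    extras:
        Optional per-caller DataFrame (keyed by caller name) with a
        ``quality`` column and one 0/1 column per named filter, aligned to
        ``sites``; NaN rows mark sites outside that caller's candidate set.
    """

    sites: list[Site]
    caller_names: list[str]
    calls: np.ndarray
    labels: np.ndarray | None = None
    features: pd.DataFrame | None = None
    extras: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.caller_names)):
            raise DataError(
                f"calls matrix shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.caller_names)} callers"
            )
        if len(set(self.sites)) != len(self.sites):
            raise DataError("duplicate sites in dataset")
        if not set(self.calls.ravel()) <= {0, 1}:
            raise DataError("calls must be binary")
        if self.n and not self.calls.any(axis=1).all():
            bad = int(np.flatnonzero(~self.calls.any(axis=1))[0])
            raise DataError(
                f"site {self.sites[bad]} detected by no caller: violates union ascertainment"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (self.n,):
                raise DataError("labels length does not match number of sites")
            if not set(self.labels.tolist()) <= {0, 1}:
                raise DataError("labels must be 0/1 (only successfully validated sites are kept)")
        if self.features is not None and len(self.features) != self.n:
            raise DataError("features table length does not match number of sites")

    @property
    def n(self) -> int:
        return len(self.sites)

    @property
    def n_callers(self) -> int:
        return len(self.caller_names)

    def caller_index(self, name: str) -> int:
        try:
            return self.caller_names.index(name)
        except ValueError:
            raise DataError(f"unknown caller {name!r}; have {self.caller_names}") from None

    def subset(self, index: np.ndarray) -> "CallDataset":
        """Row-subset (boolean mask or integer index array), preserving alignment."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CallDataset(
            sites=[self.sites[i] for i in index],
            caller_names=list(self.caller_names),
            calls=self.calls[index],
            labels=None if self.labels is None else self.labels[index],
            features=None if self.features is None else self.features.iloc[index].reset_index(drop=True),
            extras={k: v.iloc[index].reset_index(drop=True) for k, v in self.extras.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Site keys, per-caller calls and (if present) labels as one DataFrame."""
        df = pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
            }
        )
        for k, name in enumerate(self.caller_names):
            df[name] = self.calls[:, k]
        if self.labels is not None:
            df["label"] = self.labels
        return df


# ---------------------------------------------------------------------------
# readers


def read_caller_vcf(path: str | Path, caller_name: str | None = None, pass_only: bool = False) -> set[Site]:
    """Read one caller's VCF into a deduplicated set of SNV sites.

    Multiallelic records contribute one site per single-base alt allele.
    Non-SNV records (indels, MNVs, symbolic alleles) are skipped and counted
    in a log summary. By default the FILTER column is ignored — a caller's
    emitted file is taken as its final call set; ``pass_only=True`` restricts
    to FILTER=PASS records.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"VCF not found: {path}")
    name = caller_name or path.stem
    sites: set[Site] = set()
    n_records = n_skipped = 0
    for variant in VCF(str(path)):
        n_records += 1
        if pass_only and variant.FILTER is not None:
            n_skipped += 1
            continue
        ref = variant.REF.upper()
        any_snv = False
        for alt in variant.ALT:
            alt = alt.upper()
            if len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES and ref != alt:
                sites.add(Site(variant.CHROM, variant.POS, ref, alt))
                any_snv = True
        if not any_snv:
            n_skipped += 1
    logger.info(
        "%s: %d records, %d skipped (non-SNV or filtered), %d unique SNV sites",
        name, n_records, n_skipped, len(sites),
    )
    if not sites:
        logger.warning("%s: no SNV records found in %s", name, path)
    return sites


def read_sites_tsv(path: str | Path) -> set[Site]:
    """Read a 4-column (chrom, pos, ref, alt) tab-delimited call list."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ("chrom", "pos", "ref", "alt"), path)
    return {Site(r.chrom, int(r.pos), r.ref, r.alt) for r in df.itertuples()}


def read_validation_tsv(path: str | Path) -> dict[Site, int]:
    """Read the validation table; status may be somatic/non-somatic or 1/0."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "status": str})
    _require_columns(df, ("chrom", "pos", "ref", "alt", "status"), path)
    mapping = {"somatic": 1, "non-somatic": 0, "1": 1, "0": 0}
    out: dict[Site, int] = {}
    for r in df.itertuples():
        status = str(r.status).strip().lower()
        if status not in mapping:
            raise DataError(f"unrecognized validation status {r.status!r} in {path}")
        out[Site(r.chrom, int(r.pos), r.ref, r.alt)] = mapping[status]
    return out


def read_features_tsv(path: str | Path) -> dict[Site, GenomicFeatures]:
    """Read per-site genomic features (depths and VAFs); '.' or blank = missing."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["."])
    _require_columns(df, ("chrom", "pos", "ref", "alt") + NUMERIC_FEATURES, path)
    out: dict[Site, GenomicFeatures] = {}
    for r in df.itertuples():
        site = Site(r.chrom, int(r.pos), r.ref, r.alt)
        out[site] = GenomicFeatures(
            depth_tumor=None if pd.isna(r.depth_tumor) else int(r.depth_tumor),
            depth_normal=None if pd.isna(r.depth_normal) else int(r.depth_normal),
            vaf_tumor=None if pd.isna(r.vaf_tumor) else float(r.vaf_tumor),
            vaf_normal=None if pd.isna(r.vaf_normal) else float(r.vaf_normal),
            substitution=site.substitution,
        )
    return out


def read_extras_tsv(path: str | Path) -> dict[str, dict[Site, dict]]:
    """Read per-caller extras: quality score plus named 0/1 filter columns.

    Returns ``{caller: {site: {"quality": float, "filters": {name: 0/1}}}}``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "caller": str}, na_values=["."])
    _require_columns(df, ("chrom", "pos", "ref", "alt", "caller", "quality"), path)
    filter_cols = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt", "caller", "quality")]
    out: dict[str, dict[Site, dict]] = {}
    for r in df.itertuples():
        site = Site(r.chrom, int(r.pos), r.ref, r.alt)
        flags = {c: int(getattr(r, c)) for c in filter_cols}
        if not set(flags.values()) <= {0, 1}:
            raise DataError(f"filter flags must be 0/1 at {site} in {path}")
        out.setdefault(str(r.caller), {})[site] = {"quality": float(r.quality), "filters": flags}
    return out


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")


# ---------------------------------------------------------------------------
# assembly


def assemble_dataset(
    per_caller_sites: Mapping[str, Iterable[Site]],
    validation: Mapping[Site, int] | None = None,
    features: Mapping[Site, GenomicFeatures] | None = None,
    extras: Mapping[str, Mapping[Site, dict]] | None = None,
) -> CallDataset:
    """Align per-caller call sets into a union-ascertained :class:`CallDataset`.

    The site universe is the union of the caller sets; when a validation map
    is given it is intersected with the validated sites (only impartially
    validated sites carry labels, and a validated site detected by no caller
    is a consistency error). Site order is deterministic: genomic coordinate
    order, independent of input ordering.
    """
    caller_names = list(per_caller_sites)
    caller_sets = {name: set(s) for name, s in per_caller_sites.items()}
    union: set[Site] = set().union(*caller_sets.values()) if caller_sets else set()
    if validation is not None:
        orphans = sorted(set(validation) - union, key=_site_sort_key)
        if orphans:
            raise DataError(
                f"{len(orphans)} validated site(s) detected by no caller "
                f"(first: {orphans[0]}): violates union ascertainment"
            )
        universe = union & set(validation)
    else:
        universe = union
    sites = sorted(universe, key=_site_sort_key)
    calls = np.zeros((len(sites), len(caller_names)), dtype=np.int8)
    for k, name in enumerate(caller_names):
        hit = caller_sets[name]
        calls[:, k] = [1 if s in hit else 0 for s in sites]
    labels = None if validation is None else np.array([validation[s] for s in sites], dtype=np.int8)

    feat_df = None
    if features is not None:
        rows = []
        for s in sites:
            f = features.get(s)
            rows.append(
                {
                    "depth_tumor": np.nan if f is None or f.depth_tumor is None else f.depth_tumor,
                    "depth_normal": np.nan if f is None or f.depth_normal is None else f.depth_normal,
                    "vaf_tumor": np.nan if f is None or f.vaf_tumor is None else f.vaf_tumor,
                    "vaf_normal": np.nan if f is None or f.vaf_normal is None else f.vaf_normal,
                    "substitution": s.substitution,
                }
            )
            if f is not None and f.substitution is not None and f.substitution != s.substitution:
                raise DataError(f"feature substitution {f.substitution} contradicts site {s}")
        feat_df = pd.DataFrame(rows)

    extras_dfs: dict[str, pd.DataFrame] = {}
    if extras:
        for caller, per_site in extras.items():
            filter_names = sorted({name for d in per_site.values() for name in d["filters"]})
            rows = []
            for s in sites:
                d = per_site.get(s)
                row = {"quality": np.nan if d is None else d["quality"]}
                for fn in filter_names:
                    row[fn] = np.nan if d is None else d["filters"].get(fn, np.nan)
                rows.append(row)
            extras_dfs[caller] = pd.DataFrame(rows)

    return CallDataset(
        sites=sites,
        caller_names=caller_names,
        calls=calls,
        labels=labels,
        features=feat_df,
        extras=extras_dfs,
    )


# ---------------------------------------------------------------------------
# writers


def write_ranked_calls(dataset: CallDataset, scores: np.ndarray, path: str | Path) -> pd.DataFrame:
    """Write sites ranked by descending score to a tab-delimited file.

    Columns: chrom, pos, ref, alt, one 0/1 column per caller, the
    caller-combination status label, and the score. Ties are broken by
    (chrom, pos, ref, alt) lexicographic order. Returns the written frame.
    """
    from callstack.venn import combo_status

    scores = np.asarray(scores, dtype=float)
    if scores.shape != (dataset.n,):
        raise DataError(f"scores length {scores.shape} does not match {dataset.n} sites")
    df = dataset.to_frame().drop(columns=["label"], errors="ignore")
    df["status"] = [combo_status(row, dataset.caller_names).label for row in dataset.calls]
    df["score"] = scores
    df = df.sort_values(
        by=["score", "chrom", "pos", "ref", "alt"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".")
    return df


def write_caller_vcf(sites: Iterable[Site], path: str | Path) -> None:
    """Write a minimal VCF v4.2 with one record per site, coordinate-sorted."""
    ordered = sorted(set(sites), key=_site_sort_key)
    contigs = []
    for s in ordered:
        if s.chrom not in contigs:
            contigs.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in ordered:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\n")
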
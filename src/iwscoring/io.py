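"""Readers and writers for variants, score tables, region files and model artifacts.

Coordinate conventions: variants are 1-based (VCF style); BED intervals are
0-based half-open. Conversion between the two happens only inside
:func:`overlap_regions`. Chromosome names are matched verbatim ("chr1" is not
"1") unless ``normalize_chrom`` is requested. Missing score cells may be
encoded as ``NA``, ``NaN`` or an empty field on input and are written back as
``NA``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt")


class IwScoringError(Exception):
    """Base class for errors raised by this package."""


class ParseError(IwScoringError):
    """A record in an input file could not be parsed."""


class ValidationError(IwScoringError):
    """Input violated a documented precondition."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos} on {self.chrom}")
        if not self.ref or not self.alt:
            raise ValidationError(f"ref and alt must be nonempty at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SystemSpec:
    """One constituent scoring system.

    ``transform`` is ``"identity"`` or ``"neg_log2_p"`` (for systems whose raw
    output is a p-value in (0, 1], integrated on the -log2 scale).
    ``known_only`` marks systems that only score known (dbSNP-catalogued)
    variants and are therefore excluded from the novel-variant workflows.
    """

    id: str
    transform: str = "identity"
    known_only: bool = False

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "neg_log2_p"):
            raise ValidationError(f"unknown transform {self.transform!r} for system {self.id}")


#: The canonical panel of 11 noncoding scoring systems. DeepSEA reports a
#: functional-significance p-value, integrated as -log2(p); the three GWAVA
#: classifiers only score known variants.
DEFAULT_SYSTEM_SPECS: tuple[SystemSpec, ...] = (
    SystemSpec("cadd"),
    SystemSpec("deepsea", transform="neg_log2_p"),
    SystemSpec("eigen"),
    SystemSpec("eigen_pc"),
    SystemSpec("fitcons"),
    SystemSpec("funseq2"),
    SystemSpec("fathmm_mkl"),
    SystemSpec("gwava_region", known_only=True),
    SystemSpec("gwava_tss", known_only=True),
    SystemSpec("gwava_unmatched", known_only=True),
    SystemSpec("remm"),
)

_SPEC_BY_ID = {s.id: s for s in DEFAULT_SYSTEM_SPECS}


def system_spec(system_id: str) -> SystemSpec:
    """Return the canonical :class:`SystemSpec` for ``system_id``.

    Unknown identifiers get an identity-transform, not-known-only spec, so
    user-defined panels work out of the box.
    """
    return _SPEC_BY_ID.get(system_id, SystemSpec(system_id))


@dataclass
class ScoreMatrix:
    """A variants-by-systems table of real scores; NaN encodes a missing value."""

    variants: list[VariantKey]
    systems: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.variants), len(self.systems)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.variants)} variants x {len(self.systems)} systems"
            )
        if len(set(self.variants)) != len(self.variants):
            raise ValidationError("variant keys are not unique within the score matrix")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, system: str) -> np.ndarray:
        return self.values[:, self.systems.index(system)]

    def subset_systems(self, systems: Sequence[str]) -> "ScoreMatrix":
        missing = [s for s in systems if s not in self.systems]
        if missing:
            raise ValidationError(f"missing system(s): {', '.join(missing)}")
        idx = [self.systems.index(s) for s in systems]
        return ScoreMatrix(list(self.variants), list(systems), self.values[:, idx].copy())

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            [(v.chrom, v.pos, v.ref, v.alt) for v in self.variants],
            columns=list(VARIANT_COLUMNS),
        )
        scores = pd.DataFrame(self.values, columns=self.systems)
        return pd.concat([meta, scores], axis=1)

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(list(self.variants), list(self.systems), self.values.copy())


@dataclass
class RegionSet:
    """Genomic intervals (0-based half-open) with text labels."""

    intervals: list[tuple[str, int, int, str]]
    _trees: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for chrom, start, end, _label in self.intervals:
            if not (0 <= start < end):
                raise ValidationError(f"bad interval {chrom}:{start}-{end} (need 0 <= start < end)")

    def tree(self, chrom: str) -> IntervalTree:
        if not self._trees:
            for c, s, e, label in self.intervals:
                self._trees.setdefault(c, IntervalTree()).addi(s, e, label)
        return self._trees.get(chrom, IntervalTree())


def _normalize_chrom(chrom: str, mode: str | None) -> str:
    if mode == "strip":
        return chrom[3:] if chrom.startswith("chr") else chrom
    if mode == "add":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    return chrom


def read_variants(path: str | Path, format: str | None = None,
                  normalize_chrom: str | None = None) -> list[VariantKey]:
    """Read variant keys from a VCF (multi-allelic records split) or a 4-column TSV.

    Input order is preserved. ``format`` defaults from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        return _read_vcf(path, normalize_chrom)
    if format == "tsv":
        return _read_variant_tsv(path, normalize_chrom)
    raise ValidationError(f"unknown variant format {format!r}")


def _read_vcf(path: Path, normalize_chrom: str | None) -> list[VariantKey]:
    import pysam

    keys: list[VariantKey] = []
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.ref is None or not rec.alts:
                    continue
                for alt in rec.alts:
                    keys.append(VariantKey(_normalize_chrom(rec.chrom, normalize_chrom),
                                           rec.pos, rec.ref, alt))
    except (OSError, ValueError) as exc:
        raise ParseError(f"failed to parse VCF {path}: {exc}") from exc
    return keys


def _read_variant_tsv(path: Path, normalize_chrom: str | None) -> list[VariantKey]:
    keys: list[VariantKey] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:4] == list(VARIANT_COLUMNS):
                continue  # optional header row
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}")
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: position {pos_s!r} is not an integer") from exc
            try:
                keys.append(VariantKey(_normalize_chrom(chrom, normalize_chrom), pos, ref, alt))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return keys


_NA_VALUES = ["NA", "NaN", ""]


def read_score_table(path: str | Path, system_specs: Sequence[SystemSpec | str],
                     normalize_chrom: str | None = None) -> ScoreMatrix:
    """Read a score TSV (chrom, pos, ref, alt, then one column per system).

    Columns are restricted to, and ordered as, ``system_specs``; extra columns
    are ignored with a log message. Missing cells ("NA", "NaN" or empty)
    become NaN.
    """
    wanted = [s.id if isinstance(s, SystemSpec) else s for s in system_specs]
    try:
        df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False,
                         dtype={"chrom": str, "ref": str, "alt": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"failed to parse score table {path}: {exc}") from exc
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"score table {path} lacks required column {col!r}")
    absent = [s for s in wanted if s not in df.columns]
    if absent:
        raise ValidationError(f"missing system(s): {', '.join(absent)}")
    extra = [c for c in df.columns if c not in VARIANT_COLUMNS and c not in wanted]
    if extra:
        logger.warning("score table %s: ignoring unrequested column(s) %s", path, ", ".join(extra))
    for s in wanted:
        try:
            df[s] = pd.to_numeric(df[s], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"score table {path}: non-numeric value in column {s!r}: {exc}") from exc
    variants = [
        VariantKey(_normalize_chrom(str(c), normalize_chrom), int(p), str(r), str(a))
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    return ScoreMatrix(variants, wanted, df[wanted].to_numpy(dtype=float))


def read_bed(path: str | Path, normalize_chrom: str | None = None) -> RegionSet:
    """Read BED3+ intervals; column 4, when present, is the label."""
    intervals: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom = _normalize_chrom(fields[0], normalize_chrom)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            label = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            intervals.append((chrom, start, end, label))
    return RegionSet(intervals)


def overlap_regions(variants: Sequence[VariantKey], region_set: RegionSet) -> list[list[str]]:
    """Label each variant with every region containing it.

    A variant at 1-based position p overlaps interval [s, e) iff s <= p-1 < e.
    Labels are returned sorted by (start, end, label) for determinism.
    """
    out: list[list[str]] = []
    for v in variants:
        hits = region_set.tree(v.chrom).at(v.pos - 1)
        out.append([iv.data for iv in sorted(hits, key=lambda iv: (iv.begin, iv.end, str(iv.data)))])
    return out


# ---------------------------------------------------------------------------
# Scored output
# ---------------------------------------------------------------------------

def write_scored_tsv(scored: Sequence, path: str | Path) -> None:
    """Write scored variants as TSV.

    Columns: chrom, pos, ref, alt, iw_score, p_value, rank, one column per
    rescaled system value, imputed_systems (semicolon-joined), and
    ``significant`` when a threshold was applied.
    """
    if not scored:
        raise ValidationError("refusing to write an empty scored-variant table")
    systems = list(scored[0].rescaled)
    rows = []
    for sv in scored:
        row = {
            "chrom": sv.key.chrom, "pos": sv.key.pos, "ref": sv.key.ref, "alt": sv.key.alt,
            "iw_score": sv.iw_score, "p_value": sv.p_value, "rank": sv.rank,
        }
        row.update({s: sv.rescaled[s] for s in systems})
        row["imputed_systems"] = ";".join(sv.imputed_systems)
        if sv.significant is not None:
            row["significant"] = sv.significant
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_scored_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_scored_tsv`."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_VALUES, keep_default_na=False,
                     dtype={"chrom": str, "ref": str, "alt": str})
    for col in ("chrom", "pos", "ref", "alt", "iw_score", "p_value", "rank"):
        if col not in df.columns:
            raise ParseError(f"scored table {path} lacks column {col!r}")
    if "imputed_systems" in df.columns:
        df["imputed_systems"] = df["imputed_systems"].fillna("")
    return df


# ---------------------------------------------------------------------------
# Model persistence (JSON; floats round-trip exactly via repr)
# ---------------------------------------------------------------------------

def _pool_digest(values: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(values, dtype=float).tobytes()).hexdigest()


def save_model(model, path: str | Path) -> None:
    """Serialize a trained model to JSON; save/load round trips bit-exactly."""
    from .training import TrainedModel  # local import to avoid a cycle

    assert isinstance(model, TrainedModel)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "workflow_id": model.workflow_id,
        "systems": list(model.systems),
        "transforms": {s.id: s.transform for s in model.system_specs},
        "known_only": {s.id: s.known_only for s in model.system_specs},
        "rescale_params": {
            sid: {"min_a": p.min_a, "max_a": p.max_a, "min_r": p.min_r,
                  "max_r": p.max_r, "mean": p.mean, "sd": p.sd}
            for sid, p in model.rescale_params.items()
        },
        "weights": {
            "systems": list(model.weights.systems),
            "values": [float(w) for w in model.weights.values],
            "lead_eigenvalue": float(model.weights.lead_eigenvalue),
        },
        "null": {
            "family": model.null.family,
            "shift": model.null.shift,
            "meanlog": model.null.meanlog,
            "sdlog": model.null.sdlog,
            "train_mean": model.null.train_mean,
            "train_sd": model.null.train_sd,
            "sorted_scores": [float(x) for x in model.null.sorted_scores],
        },
        "reference_pool": [[float(x) for x in row] for row in model.reference_pool],
        "reference_pool_digest": _pool_digest(model.reference_pool),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path):
    """Load a model saved by :func:`save_model`."""
    from .training import NullDistribution, RescaleParams, TrainedModel, WeightVector

    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(f"unsupported model schema_version {version!r} (expected {SCHEMA_VERSION})")
    systems = list(doc["systems"])
    specs = tuple(
        SystemSpec(sid, transform=doc["transforms"][sid], known_only=doc["known_only"][sid])
        for sid in systems
    )
    rescale = {
        sid: RescaleParams(**params) for sid, params in doc["rescale_params"].items()
    }
    w = doc["weights"]
    weights = WeightVector(tuple(w["systems"]), np.asarray(w["values"], dtype=float),
                           float(w["lead_eigenvalue"]))
    n = doc["null"]
    null = NullDistribution(
        family=n["family"], shift=n["shift"], meanlog=n["meanlog"], sdlog=n["sdlog"],
        sorted_scores=np.asarray(n["sorted_scores"], dtype=float),
        train_mean=n["train_mean"], train_sd=n["train_sd"],
    )
    pool = np.asarray(doc["reference_pool"], dtype=float)
    if pool.size == 0:
        pool = pool.reshape(0, len(systems))
    if _pool_digest(pool) != doc["reference_pool_digest"]:
        raise ValidationError(f"reference pool digest mismatch in {path}")
    return TrainedModel(
        workflow_id=doc["workflow_id"], system_specs=specs, rescale_params=rescale,
        weights=weights, null=null, reference_pool=pool,
    )
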
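"""I/O and ratio arithmetic for protein-level TMT quantification tables.

The analysis unit throughout the package is the protein subgroup as exported
by the search engine: one row per protein with a gene symbol, the number of
distinct peptides, a search-engine protein score, and one numeric column per
TMT channel.  Channel values may be raw reporter-ion intensities or mean
ratios relative to a base channel; because every downstream comparison is a
ratio of two channels, both conventions give identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reporter channels of a TMT 11-plex cassette, in mass order.
TMT11_CHANNELS = (
    "126C", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131N", "131C",
)

#: Columns every quantification table must carry before the channel columns.
REQUIRED_COLUMNS = ("protein_id", "gene_symbol", "n_distinct_peptides", "protein_score")

CHANNEL_ROLES = ("experimental", "background_control", "spatial_reference", "omit_crosslink_control")
COMPARISON_TYPES = ("background", "reference", "crosslink")


class FormatError(ValueError):
    """A delimited input file does not have the expected shape."""


class ValidationError(ValueError):
    """An input parses but violates a contract (duplicates, bad labels...)."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase, whitespace-stripped gene symbol used for all set matching."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# experiment design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioPair:
    """One enrichment comparison: numerator channel over denominator channel."""

    numerator: str
    denominator: str
    replicate_id: int
    comparison_type: str = "background"

    def __post_init__(self):
        if self.numerator == self.denominator:
            raise ValidationError(f"ratio pair {self.numerator}/{self.denominator}: channels must differ")
        if self.comparison_type not in COMPARISON_TYPES:
            raise ValidationError(f"unknown comparison type {self.comparison_type!r}")

    @property
    def column(self) -> str:
        return f"{self.numerator}/{self.denominator}"


@dataclass
class ExperimentDesign:
    """Channel roles and the ratio pairings that define each biological replicate.

    ``min_replicates_k`` is the cross-replicate support rule: a protein enters
    the final proteome only if it survives filtering in at least k replicates.
    """

    channels: list[tuple[str, str]]                 # (label, role)
    comparisons: list[RatioPair]
    min_replicates_k: int = 2
    detection_min_peptides: int = 2
    detection_min_score: float = 20.0

    def __post_init__(self):
        labels = [c[0] for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate channel labels in design")
        for _, role in self.channels:
            if role not in CHANNEL_ROLES:
                raise ValidationError(f"unknown channel role {role!r}")
        known = set(labels)
        for pair in self.comparisons:
            for lab in (pair.numerator, pair.denominator):
                if lab not in known:
                    raise ValidationError(f"comparison channel {lab!r} not declared in design")
        reps = self.replicate_ids()
        if not reps:
            raise ValidationError("design declares no comparisons")
        if not (1 <= self.min_replicates_k <= len(reps)):
            raise ValidationError(
                f"min_replicates_k={self.min_replicates_k} outside 1..{len(reps)}"
            )

    def replicate_ids(self) -> list[int]:
        return sorted({p.replicate_id for p in self.comparisons})

    def comparisons_for(self, replicate_id: int) -> list[RatioPair]:
        return [p for p in self.comparisons if p.replicate_id == replicate_id]

    def channel_labels(self, role: str | None = None) -> list[str]:
        return [lab for lab, r in self.channels if role is None or r == role]

    # -- JSON round trip -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "channels": [{"label": lab, "role": role} for lab, role in self.channels],
            "comparisons": [
                {"num": p.numerator, "den": p.denominator,
                 "replicate": p.replicate_id, "type": p.comparison_type}
                for p in self.comparisons
            ],
            "min_replicates_k": self.min_replicates_k,
            "detection": {
                "min_peptides": self.detection_min_peptides,
                "min_score": self.detection_min_score,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExperimentDesign":
        det = d.get("detection", {})
        return cls(
            channels=[(c["label"], c["role"]) for c in d["channels"]],
            comparisons=[
                RatioPair(c["num"], c["den"], int(c["replicate"]), c.get("type", "background"))
                for c in d["comparisons"]
            ],
            min_replicates_k=int(d.get("min_replicates_k", 2)),
            detection_min_peptides=int(det.get("min_peptides", 2)),
            detection_min_score=float(det.get("min_score", 20.0)),
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# quantification table
# ---------------------------------------------------------------------------

@dataclass
class QuantTable:
    """Protein-level quantification records plus the list of channel columns.

    ``data`` holds one row per protein subgroup; channel values are
    nonnegative reals with missing values carried as NaN (never silently 0).
    """

    data: pd.DataFrame
    channels: list[str] = field(default_factory=list)

    def __post_init__(self):
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise FormatError(f"{col} absent")
        if not self.channels:
            self.channels = [c for c in self.data.columns if c not in REQUIRED_COLUMNS]
        if not self.channels:
            raise FormatError("no channel columns")
        vals = self.data[self.channels].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValidationError("negative channel values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.data["gene_symbol"])

    def gene_universe(self) -> set[str]:
        return set(self.data["gene_symbol"])


def read_quant_table(path: str | Path, *, strict: bool = True, sep: str = "\t") -> QuantTable:
    """Read a delimited quantification table with a header row.

    Gene symbols are normalized (uppercase, stripped).  Under ``strict`` mode
    two rows that collide after normalization raise a :class:`ValidationError`
    listing the colliding symbols; otherwise the row with the highest protein
    score is kept per symbol.  Row order is preserved.
    """
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{col} absent")
    df = df.copy()
    df["gene_symbol"] = df["gene_symbol"].map(normalize_symbol)
    dup = df["gene_symbol"][df["gene_symbol"].duplicated()].unique()
    if len(dup):
        if strict:
            raise ValidationError("duplicate gene symbols after normalization: "
                                  + ", ".join(sorted(dup)))
        logger.info("merging %d duplicate symbols (keeping highest protein score)", len(dup))
        df = (df.sort_values("protein_score", ascending=False)
                .drop_duplicates("gene_symbol", keep="first")
                .sort_index())
    df = df.reset_index(drop=True)
    return QuantTable(df)


def write_quant_table(table: QuantTable, path: str | Path, *, sep: str = "\t") -> None:
    cols = list(REQUIRED_COLUMNS) + list(table.channels)
    table.data[cols].to_csv(path, sep=sep, index=False)


def apply_detection_filter(table: QuantTable,
                           min_peptides: int = 2,
                           min_score: float = 20.0) -> QuantTable:
    """Keep proteins with >= min_peptides distinct peptides AND score >= min_score.

    Both thresholds are inclusive.  The defaults retain proteins identified by
    two or more distinct peptides with a protein score of at least 20 — the
    standard confidence filter for search-engine protein subgroups.
    """
    if min_peptides < 0 or min_score < 0:
        raise ValidationError("detection thresholds must be nonnegative")
    keep = ((table.data["n_distinct_peptides"] >= min_peptides)
            & (table.data["protein_score"] >= min_score))
    return QuantTable(table.data[keep].reset_index(drop=True), list(table.channels))


# ---------------------------------------------------------------------------
# ratio table
# ---------------------------------------------------------------------------

@dataclass
class RatioTable:
    """Per-gene enrichment ratios, one column per configured comparison.

    Missing ratios (zero or missing denominator, missing numerator) are NaN.
    """

    values: pd.DataFrame                 # index: gene_symbol, columns: pair.column
    pairs: list[RatioPair]

    def column(self, pair: RatioPair) -> pd.Series:
        return self.values[pair.column]

    def ratios_for(self, pair: RatioPair) -> dict[str, float]:
        """Finite ratios for one comparison as a gene -> ratio mapping."""
        col = self.values[pair.column]
        return {g: v for g, v in col.items() if np.isfinite(v)}

    def transform(self, func) -> "RatioTable":
        """Apply an elementwise map to every ratio (used for invariance checks)."""
        out = self.values.copy()
        mask = np.isfinite(out.to_numpy(dtype=float))
        arr = out.to_numpy(dtype=float)
        arr[mask] = [func(v) for v in arr[mask]]
        return RatioTable(pd.DataFrame(arr, index=out.index, columns=out.columns), list(self.pairs))


def compute_ratios(table: QuantTable, design: ExperimentDesign,
                   *, median_center: bool = False) -> RatioTable:
    """Compute the per-comparison enrichment ratio for every protein.

    ``ratio = numerator / denominator`` per row.  A zero or missing
    denominator (or missing numerator) yields NaN with a logged count — never
    0 and never infinity.  When the exported channel values are themselves
    ratios to a common base channel, dividing two of them equals the direct
    channel division, so no special casing is needed.

    ``median_center`` optionally divides each channel column by its median
    before forming ratios (off by default; whether the upstream export was
    median-normalized is not generally knowable from the table itself).
    """
    df = table.data.set_index("gene_symbol")
    chan = df[table.channels].astype(float)
    if median_center:
        med = chan.median(axis=0, skipna=True)
        med = med.replace(0, np.nan)
        chan = chan / med
    out = {}
    for pair in design.comparisons:
        num = chan[pair.numerator].to_numpy()
        den = chan[pair.denominator].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((den > 0) & np.isfinite(den) & np.isfinite(num), num / den, np.nan)
        n_missing = int(np.isnan(ratio).sum())
        if n_missing:
            logger.warning("comparison %s: %d missing ratios", pair.column, n_missing)
        out[pair.column] = ratio
    values = pd.DataFrame(out, index=df.index)
    return RatioTable(values, list(design.comparisons))


def crosslink_dependence_ratios(table: QuantTable, design: ExperimentDesign) -> dict[str, float]:
    """+crosslink / -crosslink enrichment ratio per gene.

    Mean of the experimental channel values over the mean of the
    omit-crosslink control channel values.  Low values flag tight binders
    that survive phase separation without chemical crosslinking.
    """
    exp = design.channel_labels("experimental")
    ctl = design.channel_labels("omit_crosslink_control")
    if not exp or not ctl:
        raise ValidationError("design lacks experimental or omit-crosslink channels")
    df = table.data.set_index("gene_symbol")
    num = df[exp].astype(float).mean(axis=1)
    den = df[ctl].astype(float).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den.replace(0, np.nan)
    return {g: float(v) for g, v in ratio.items() if np.isfinite(v)}


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

_HEADER_TOKENS = {"gene", "genes", "symbol", "gene_symbol"}


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list: one symbol per line, '#' comments allowed.

    Symbols are normalized and deduplicated; an optional single header line
    (``gene``/``gene_symbol``/...) is skipped.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if lines and lines[0].lower() in _HEADER_TOKENS:
        lines = lines[1:]
    symbols = [normalize_symbol(ln) for ln in lines]
    out = set(symbols)
    if not out:
        warnings.warn(f"empty gene list: {path}")
    n_dup = len(symbols) - len(out)
    if n_dup:
        logger.info("%s: dropped %d duplicate symbols", path, n_dup)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    """Write a gene set sorted, one symbol per line, newline-terminated."""
    body = "\n".join(sorted(normalize_symbol(g) for g in genes))
    Path(path).write_text(body + "\n" if body else "")
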
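"""Domain types, readers/writers, coverage normalization, and validation.

The substrate of every downstream stage is an :class:`AbundanceMatrix` —
viral populations (vOTU representatives) by time-ordered samples, holding
trimmed-mean coverages normalized per 10^9 quality-trimmed ("clean") reads.
Samples carry a clock time anchored at a 16:00 local series start, an
inclusion mask (the measure sequence: scheduled time points that yielded
usable samples), and the clean-read depth used for normalization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Sample",
    "AbundanceMatrix",
    "HostTable",
    "load_abundance",
    "write_abundance",
    "load_metadata",
    "write_metadata",
    "normalize_coverage",
    "load_host_table",
    "SERIES_START_MINUTES",
]

logger = logging.getLogger(__name__)

#: The series starts at 16:00 local time; clock times derive from elapsed hours.
SERIES_START_MINUTES = 16 * 60

_LAYERS = ("SUR", "DCM")


@dataclass(frozen=True)
class Sample:
    """One scheduled sampling time point of one depth layer.

    Parameters
    ----------
    sample_id : str
        Unique sample label (column header of the abundance table).
    depth_layer : {"SUR", "DCM"}
        Surface mixed layer or deep chlorophyll maximum.
    clock_time : int
        Local time of day in minutes since midnight.
    elapsed_hours : float
        Hours since the series start (16:00 on day 0).
    included : bool
        Measure-sequence flag; False marks a scheduled point excluded from
        analysis (the sample itself is retained in files and metadata).
    clean_reads : int
        Quality-trimmed read count of the sample; normalization denominator.
    """

    sample_id: str
    depth_layer: str
    clock_time: int
    elapsed_hours: float
    included: bool
    clean_reads: int

    def __post_init__(self) -> None:
        if self.depth_layer not in _LAYERS:
            raise ValueError(
                f"depth_layer must be one of {_LAYERS}, got {self.depth_layer!r}"
            )
        if self.elapsed_hours < 0:
            raise ValueError("elapsed_hours must be >= 0")
        if not (0 <= self.clock_time < 24 * 60):
            raise ValueError("clock_time must be in [0, 1440) minutes")
        if self.clean_reads <= 0:
            raise ValueError(f"clean_reads must be > 0 for {self.sample_id!r}")

    @property
    def clock_hours(self) -> float:
        """Clock time of day in hours."""
        return self.clock_time / 60.0


def clock_from_elapsed(elapsed_hours: float) -> int:
    """Minutes-since-midnight clock time for an elapsed hour offset."""
    return int(round((SERIES_START_MINUTES + elapsed_hours * 60) % (24 * 60)))


@dataclass
class AbundanceMatrix:
    """Populations-by-samples normalized coverage table.

    ``values[i, j]`` is the abundance of ``population_ids[i]`` in
    ``samples[j]`` (trimmed-mean coverage per 10^9 clean reads, or raw
    coverage if normalization has not been applied yet).
    """

    population_ids: list[str]
    samples: list[Sample]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.population_ids), len(self.samples)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.population_ids)} populations x {len(self.samples)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("abundances must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("abundances must be finite")
        if len(set(self.population_ids)) != len(self.population_ids):
            dupes = pd.Index(self.population_ids)
            raise ValueError(
                "duplicate population ids: "
                f"{sorted(dupes[dupes.duplicated()].unique())}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        for layer in _LAYERS:
            t = [s.elapsed_hours for s in self.samples if s.depth_layer == layer]
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError(
                    f"elapsed_hours not strictly increasing within layer {layer}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def included_mask(self) -> np.ndarray:
        """Boolean vector over columns: the measure sequence."""
        return np.array([s.included for s in self.samples], dtype=bool)

    def subset_layer(self, layer: str) -> "AbundanceMatrix":
        """Restrict to one depth layer, keeping column order."""
        if layer not in _LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        keep = [j for j, s in enumerate(self.samples) if s.depth_layer == layer]
        return AbundanceMatrix(
            population_ids=list(self.population_ids),
            samples=[self.samples[j] for j in keep],
            values=self.values[:, keep],
        )

    def subset_populations(self, ids: list[str]) -> "AbundanceMatrix":
        index = {p: i for i, p in enumerate(self.population_ids)}
        missing = [p for p in ids if p not in index]
        if missing:
            raise KeyError(f"unknown population ids: {missing[:5]}")
        rows = [index[p] for p in ids]
        return AbundanceMatrix(
            population_ids=list(ids),
            samples=list(self.samples),
            values=self.values[rows, :],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.population_ids, columns=self.sample_ids
        )


@dataclass
class HostTable:
    """Best genus-level host prediction per viral population."""

    genus: dict[str, str]
    confidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop in self.confidence:
            if pop not in self.genus:
                raise ValueError(f"confidence for unknown population {pop!r}")

    def __len__(self) -> int:
        return len(self.genus)

    def __contains__(self, population_id: str) -> bool:
        return population_id in self.genus


# ---------------------------------------------------------------------------
# Metadata I/O


def _parse_clock(text: str) -> int:
    m = re.fullmatch(r"(\d{1,2}):(\d{2})", str(text).strip())
    if not m:
        raise ValueError(f"clock_time must be HH:MM, got {text!r}")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh >= 24 or mm >= 60:
        raise ValueError(f"invalid clock_time {text!r}")
    return hh * 60 + mm


def _format_clock(minutes: int) -> str:
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def load_metadata(path) -> list[Sample]:
    """Read a sample-metadata CSV into a list of :class:`Sample`.

    Expected columns: sample_id, depth_layer, clock_time (HH:MM),
    elapsed_hours, included (0/1), clean_reads.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "clock_time": str})
    required = {
        "sample_id",
        "depth_layer",
        "clock_time",
        "elapsed_hours",
        "included",
        "clean_reads",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    samples = [
        Sample(
            sample_id=row.sample_id,
            depth_layer=str(row.depth_layer),
            clock_time=_parse_clock(row.clock_time),
            elapsed_hours=float(row.elapsed_hours),
            included=bool(int(row.included)),
            clean_reads=int(row.clean_reads),
        )
        for row in df.itertuples(index=False)
    ]
    return samples


def write_metadata(samples: list[Sample], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "depth_layer": [s.depth_layer for s in samples],
            "clock_time": [_format_clock(s.clock_time) for s in samples],
            "elapsed_hours": [s.elapsed_hours for s in samples],
            "included": [int(s.included) for s in samples],
            "clean_reads": [s.clean_reads for s in samples],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Abundance I/O


def load_abundance(path, metadata_path) -> AbundanceMatrix:
    """Read a dense population-by-sample TSV plus its sample metadata.

    The TSV's first column holds population ids; remaining columns are
    samples, every one of which must be described in the metadata. Samples
    are ordered by elapsed hours within depth layer (SUR first).
    """
    samples = load_metadata(metadata_path)
    by_id = {s.sample_id: s for s in samples}
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in by_id]
    if unknown:
        raise ValueError(f"abundance columns missing from metadata: {unknown}")
    if df.index.duplicated().any():
        raise ValueError(
            f"duplicate population ids: {sorted(df.index[df.index.duplicated()])}"
        )
    if (df.values < 0).any():
        raise ValueError("negative abundance value in table")
    present = [by_id[c] for c in df.columns]
    order = sorted(
        range(len(present)),
        key=lambda j: (_LAYERS.index(present[j].depth_layer), present[j].elapsed_hours),
    )
    ordered = [present[j] for j in order]
    values = df.values[:, order]
    return AbundanceMatrix(
        population_ids=list(df.index), samples=ordered, values=values
    )


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    """Write the dense TSV form (header ``population_id<TAB>sample...``)."""
    df = matrix.to_frame()
    df.index.name = "population_id"
    # shortest-repr floats keep load(write(m)) bit-exact
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def normalize_coverage(raw: np.ndarray, samples: list[Sample],
                       population_ids: list[str] | None = None) -> AbundanceMatrix:
    """Normalize raw trimmed-mean coverages by sequencing depth.

    ``value[i, j] = raw[i, j] / clean_reads[j] * 1e9`` — coverage per 10^9
    quality-trimmed reads, which removes between-sample sequencing-effort
    differences.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != len(samples):
        raise ValueError(
            f"raw has {raw.shape} but {len(samples)} samples were given"
        )
    if np.any(raw < 0):
        raise ValueError("raw coverages must be nonnegative")
    depths = np.array([s.clean_reads for s in samples], dtype=float)
    if np.any(depths <= 0):
        raise ValueError("all clean_reads must be positive")
    if population_ids is None:
        population_ids = [f"vOTU_{i + 1}" for i in range(raw.shape[0])]
    values = raw / depths[np.newaxis, :] * 1e9
    return AbundanceMatrix(
        population_ids=list(population_ids), samples=list(samples), values=values
    )


# ---------------------------------------------------------------------------
# Host predictions


def _genus_from_taxonomy(taxonomy: str) -> str | None:
    """Lowest-rank genus from a taxonomy string.

    Accepts GTDB-style strings (``d__...;p__...;...;g__Pelagibacter;s__...``)
    or plain semicolon-separated lineages whose last informative token is
    the genus.
    """
    if taxonomy is None or (isinstance(taxonomy, float) and np.isnan(taxonomy)):
        return None
    parts = [p.strip() for p in str(taxonomy).split(";") if p.strip()]
    if not parts:
        return None
    tagged = {p[:3]: p[3:] for p in parts if re.match(r"^[a-z]__", p)}
    if tagged:
        genus = tagged.get("g__", "")
        return genus if genus else None
    # untagged lineage: last token, unless it looks like a species binomial
    last = parts[-1]
    return last if last else None


_VIRUS_COLS = ("Virus", "virus", "virus_id", "population_id", "Virus name")
_HOST_COLS = ("Host genus", "Host taxonomy", "host_taxonomy", "taxonomy", "host_genus")
_CONF_COLS = ("Confidence score", "confidence", "Main method agreement", "score")


def load_host_table(path) -> HostTable:
    """Read an iPHoP-style host-prediction CSV into a :class:`HostTable`.

    Keeps one genus per population: the highest-confidence prediction, ties
    resolved by first occurrence. Rows whose taxonomy has no parseable genus
    are skipped with a warning.
    """
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        return HostTable(genus={})
    vcol = next((c for c in _VIRUS_COLS if c in df.columns), None)
    hcol = next((c for c in _HOST_COLS if c in df.columns), None)
    if vcol is None or hcol is None:
        raise ValueError(
            f"host table needs a virus column ({_VIRUS_COLS}) and a "
            f"taxonomy column ({_HOST_COLS}); found {list(df.columns)}"
        )
    ccol = next((c for c in _CONF_COLS if c in df.columns), None)
    genus: dict[str, str] = {}
    confidence: dict[str, float] = {}
    for _, row in df.iterrows():
        pop = str(row[vcol])
        g = _genus_from_taxonomy(row[hcol])
        if g is None:
            logger.warning("skipping host row with unparseable taxonomy: %r",
                           row[hcol])
            continue
        conf = float(row[ccol]) if ccol is not None and pd.notna(row[ccol]) else 0.0
        if pop in genus and conf <= confidence.get(pop, 0.0):
            continue  # keep highest confidence; ties keep first occurrence
        genus[pop] = g
        confidence[pop] = conf
    return HostTable(genus=genus, confidence=confidence)


def validate(matrix: AbundanceMatrix) -> list[str]:
    """Return a list of invariant violations (empty when valid).

    Construction already enforces most invariants; this re-checks them on a
    possibly hand-built object and adds spacing checks per depth layer.
    """
    problems: list[str] = []
    for layer, spacing in (("SUR", 4.0), ("DCM", 12.0)):
        t = [s.elapsed_hours for s in matrix.samples if s.depth_layer == layer]
        gaps = {round(b - a, 6) for a, b in zip(t, t[1:])}
        if gaps and gaps != {spacing}:
            problems.append(
                f"{layer} spacing is {sorted(gaps)} h, expected {spacing} h"
            )
    for s in matrix.samples:
        expected = clock_from_elapsed(s.elapsed_hours)
        if s.clock_time != expected:
            problems.append(
                f"{s.sample_id}: clock_time {_format_clock(s.clock_time)} "
                f"inconsistent with elapsed {s.elapsed_hours} h "
                f"(expected {_format_clock(expected)})"
            )
    return problems
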
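"""Synthetic virome time series with known ground truth.

Emulates the study design the analysis assumes: a 112-hour Lagrangian
series sampled every 4 h at the surface (SUR, 29 scheduled points, two
masked) and every 12 h at the deep chlorophyll maximum (DCM, 10 points,
two masked), starting 16:00 local time. Diel populations follow

    value(t) = exp(b + s*t + eps_t) * w(clock(t))

where ``w`` is a 24-h-periodic waveform with a chosen peak clock time,
asymmetric rise/fall, and max/min ratio equal to the archetype amplitude;
non-diel populations omit ``w``. Noise is multiplicative log-normal
(``eps_t ~ N(0, noise_sd)``) because the pipeline consumes continuous
normalized coverages, not counts. The default waveform is a piecewise
log-linear circular "umbrella" (rise then fall), matching the alternative
the rhythm test is built around; a cosine option exists for robustness
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    AbundanceMatrix,
    HostTable,
    Sample,
    clock_from_elapsed,
)

__all__ = [
    "Archetype",
    "SyntheticConfig",
    "GroundTruth",
    "sampling_scheme",
    "SUR_MEASURE_SEQUENCE",
    "DCM_MEASURE_SEQUENCE",
    "umbrella_waveform",
    "cosine_waveform",
    "simulate_abundance",
    "simulate_fixtures",
]

# Measure sequences: which scheduled time points yielded usable samples.
# SUR drops the scheduled points at elapsed 52 h and 88 h; DCM drops 0 h and 24 h.
SUR_MEASURE_SEQUENCE = (
    1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 0, 1,
    1, 1, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1,
)
DCM_MEASURE_SEQUENCE = (0, 1, 0, 1, 1, 1, 1, 1, 1, 1)

_SCHEMES = {
    "SUR": (4.0, SUR_MEASURE_SEQUENCE),
    "DCM": (12.0, DCM_MEASURE_SEQUENCE),
}

#: Default clean-read depth for simulated samples (median-scale for the design).
DEFAULT_CLEAN_READS = 62_381_078


def sampling_scheme(layer: str, clean_reads: int = DEFAULT_CLEAN_READS) -> list[Sample]:
    """The packaged SUR or DCM sampling design.

    SUR: 29 samples at 0, 4, ..., 112 h (27 included); DCM: 10 samples at
    0, 12, ..., 108 h (8 included). Clock times are anchored at 16:00.
    """
    if layer not in _SCHEMES:
        raise ValueError(f"layer must be SUR or DCM, got {layer!r}")
    deltat, mask = _SCHEMES[layer]
    tag = layer[0]
    return [
        Sample(
            sample_id=f"T{int(i * deltat)}_{tag}",
            depth_layer=layer,
            clock_time=clock_from_elapsed(i * deltat),
            elapsed_hours=i * deltat,
            included=bool(m),
            clean_reads=clean_reads,
        )
        for i, m in enumerate(mask)
    ]


@dataclass(frozen=True)
class Archetype:
    """One planted diel waveform family.

    peak_clock_time : hours in [0, 24) at which the waveform peaks.
    rise_hours : duration of the rise from trough to peak (fall = 24 - rise).
    amplitude : max/min ratio of the waveform, >= 1.
    weight : proportion of diel populations drawn from this archetype.
    """

    peak_clock_time: float
    rise_hours: float
    amplitude: float
    weight: float

    def __post_init__(self) -> None:
        if not (0 <= self.peak_clock_time < 24):
            raise ValueError("peak_clock_time must be in [0, 24)")
        if not (0 < self.rise_hours < 24):
            raise ValueError("rise_hours must be in (0, 24)")
        if self.amplitude < 1:
            raise ValueError("amplitude must be >= 1")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")


#: Study-condition archetypes: two night peaks (20:00, 04:00) dominating and
#: a minority day peak (12:00), amplitude 4, 8-hour rise.
DEFAULT_ARCHETYPES = (
    Archetype(20.0, 8.0, 4.0, 0.4),
    Archetype(4.0, 8.0, 4.0, 0.4),
    Archetype(12.0, 8.0, 4.0, 0.2),
)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the packaged study conditions."""

    n_populations: int = 300
    fraction_diel: float = 0.5
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    trend_slope_sd: float = 0.005  # per-hour drift scale on the log scale
    noise_sd: float = 0.3  # log-scale multiplicative noise sd
    baseline_log_mean: float = 3.0  # ln of typical normalized coverage
    baseline_log_sd: float = 1.0
    scheme: str = "SUR"
    waveform: str = "umbrella"  # or "cosine"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_diel <= 1):
            raise ValueError("fraction_diel must be in [0, 1]")
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        w = sum(a.weight for a in self.archetypes)
        if self.fraction_diel > 0 and abs(w - 1.0) > 1e-9:
            raise ValueError(f"archetype weights must sum to 1, got {w}")
        if self.waveform not in ("umbrella", "cosine"):
            raise ValueError("waveform must be 'umbrella' or 'cosine'")
        if self.noise_sd < 0 or self.trend_slope_sd < 0:
            raise ValueError("noise_sd and trend_slope_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "archetypes" in raw:
            raw["archetypes"] = tuple(
                Archetype(**a) for a in raw["archetypes"]
            )
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-population simulation truth."""

    population_ids: list[str]
    is_diel: np.ndarray  # bool per population
    true_peak_clock_time: np.ndarray  # hours; NaN for non-diel
    archetype_id: np.ndarray  # int index; -1 for non-diel

    def __post_init__(self) -> None:
        nd = ~np.asarray(self.is_diel, dtype=bool)
        if not np.all(np.isnan(self.true_peak_clock_time[nd])):
            raise ValueError("non-diel populations must have NaN peak time")
        if not np.all(self.archetype_id[nd] == -1):
            raise ValueError("non-diel populations must have archetype -1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "population_id": self.population_ids,
                "is_diel": self.is_diel.astype(int),
                "true_peak_clock_time": self.true_peak_clock_time,
                "archetype_id": self.archetype_id,
            }
        )


def umbrella_waveform(clock_hours: np.ndarray, peak: float, rise: float,
                      amplitude: float) -> np.ndarray:
    """Piecewise log-linear circular rise/fall waveform in [1, amplitude].

    Log-amplitude climbs linearly over ``rise`` hours from the trough
    (``peak - rise`` mod 24) to the peak, then declines linearly over the
    remaining ``24 - rise`` hours.
    """
    clock = np.asarray(clock_hours, dtype=float) % 24.0
    since_trough = (clock - (peak - rise)) % 24.0
    frac = np.where(
        since_trough <= rise,
        since_trough / rise,
        1.0 - (since_trough - rise) / (24.0 - rise),
    )
    return np.exp(np.log(amplitude) * frac)


def cosine_waveform(clock_hours: np.ndarray, peak: float, rise: float,
                    amplitude: float) -> np.ndarray:
    """Symmetric log-cosine waveform in [1, amplitude] (rise is ignored)."""
    clock = np.asarray(clock_hours, dtype=float)
    phase = 2 * np.pi * (clock - peak) / 24.0
    return np.exp(np.log(amplitude) * (np.cos(phase) + 1) / 2)


_WAVEFORMS = {"umbrella": umbrella_waveform, "cosine": cosine_waveform}


def simulate_abundance(config: SyntheticConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Draw an abundance matrix plus ground truth under ``config``.

    Masked samples are simulated like any other and carry ``included=False``,
    so analyses can be compared with and without the mask. Identical seeds
    produce identical output.
    """
    rng = np.random.default_rng(config.seed)
    if config.scheme in _SCHEMES:
        samples = sampling_scheme(config.scheme)
    else:
        raise ValueError(f"unknown scheme {config.scheme!r}")
    t = np.array([s.elapsed_hours for s in samples])
    clock = np.array([s.clock_hours for s in samples])

    n = config.n_populations
    n_diel = int(round(config.fraction_diel * n))
    is_diel = np.zeros(n, dtype=bool)
    is_diel[:n_diel] = True

    weights = np.array([a.weight for a in config.archetypes], dtype=float)
    archetype_id = np.full(n, -1, dtype=int)
    if n_diel:
        archetype_id[:n_diel] = rng.choice(
            len(config.archetypes), size=n_diel, p=weights / weights.sum()
        )

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n)
    slope = rng.normal(0.0, config.trend_slope_sd, size=n)
    eps = rng.normal(0.0, config.noise_sd, size=(n, len(samples)))

    log_values = baseline[:, None] + slope[:, None] * t[None, :] + eps
    wave = _WAVEFORMS[config.waveform]
    true_peak = np.full(n, np.nan)
    for i in range(n_diel):
        a = config.archetypes[archetype_id[i]]
        log_values[i] += np.log(
            wave(clock, a.peak_clock_time, a.rise_hours, a.amplitude)
        )
        true_peak[i] = a.peak_clock_time

    ids = [f"vOTU_{i + 1:05d}" for i in range(n)]
    matrix = AbundanceMatrix(
        population_ids=ids, samples=samples, values=np.exp(log_values)
    )
    truth = GroundTruth(
        population_ids=ids,
        is_diel=is_diel,
        true_peak_clock_time=true_peak,
        archetype_id=archetype_id,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Annotation / host fixtures for the AMG rule engine and host summaries


def _fixture_annotation_frame() -> pd.DataFrame:
    """Toy gene-annotation table covering every curation-rule branch.

    Synthetic records (no real contigs): each rule of the conservative AMG
    filter has at least one record failing it alone, plus fully passing
    records.
    """
    cols = [
        "gene_id", "contig_id", "auxiliary_score", "flags", "kegg_ko",
        "metabolic_module", "in_viral_region", "contig_virus_score",
        "near_phage_end", "trna_overlap", "repeat_overlap", "contig_annotations",
    ]
    rows = [
        # all rules pass
        ("g01", "c01", 2, "M", "K06217", 1, 1, 0.99, 0, 0, 0, "phoH family protein"),
        # R1 fail: score 4
        ("g02", "c02", 4, "M", "K02703", 1, 1, 0.99, 0, 0, 0, "photosystem II"),
        # R2 fail: no module, no M/K/E flag
        ("g03", "c03", 2, "F", "K05979", 0, 1, 0.99, 0, 0, 0, "hypothetical"),
        # R3 fail: outside viral region, low contig score
        ("g04", "c04", 1, "K", "K07336", 1, 0, 0.80, 0, 0, 0, "oxygenase"),
        # R4 fail: contig carries an integrase
        ("g05", "c05", 2, "E", "K00001", 1, 1, 0.99, 0, 0, 0,
         "site-specific integrase; tail fiber"),
        # R5 fail: near phage end with tRNA overlap
        ("g06", "c06", 3, "M", "K00002", 1, 1, 0.99, 1, 1, 0, "kinase"),
        # R6 fail: no KEGG KO
        ("g07", "c07", 1, "M", "", 1, 1, 0.99, 0, 0, 0, "sulfatase"),
        # passes: score 3, flag K, contig score gate (not in viral region)
        ("g08", "c08", 3, "K", "K09882", 0, 0, 0.97, 0, 0, 0, "cobS"),
        # passes: near phage end but no tRNA/repeat overlap
        ("g09", "c09", 1, "E", "K00003", 0, 1, 0.99, 1, 0, 0, "dehydrogenase"),
        # R4 fail: glycosyltransferase keyword on contig
        ("g10", "c10", 2, "M", "K00004", 1, 1, 0.99, 0, 0, 0,
         "Glycosyltransferase family 2"),
        # passes: metabolic module without M/K/E flag
        ("g11", "c11", 2, "V", "K00005", 1, 1, 0.99, 0, 0, 0, "reductase"),
        # passes: in viral region despite low contig score
        ("g12", "c12", 1, "M", "K00006", 1, 1, 0.60, 0, 0, 0, "transferase"),
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_fixtures(
    seed: int, host_genus_freqs: dict[str, float] | None = None,
    n_populations: int = 20,
) -> tuple[pd.DataFrame, HostTable]:
    """Deterministic toy annotation table and host table.

    The annotation table covers every AMG-filter branch; the host table
    assigns genera to synthetic populations with the requested frequencies
    (default A 0.6 / B 0.3 / C 0.1). Same seed, same output.
    """
    rng = np.random.default_rng(seed)
    annotations = _fixture_annotation_frame()
    if host_genus_freqs is None:
        host_genus_freqs = {"GenusA": 0.6, "GenusB": 0.3, "GenusC": 0.1}
    genera = list(host_genus_freqs)
    freqs = np.array([host_genus_freqs[g] for g in genera], dtype=float)
    counts = np.floor(freqs * n_populations).astype(int)
    # distribute any remainder to the largest fractional parts
    short = n_populations - counts.sum()
    order = np.argsort(-(freqs * n_populations - counts))
    counts[order[:short]] += 1
    assignment = np.repeat(np.arange(len(genera)), counts)
    rng.shuffle(assignment)
    genus = {
        f"vOTU_{i + 1:05d}": genera[a] for i, a in enumerate(assignment)
    }
    confidence = {p: float(c) for p, c in
                  zip(genus, np.round(rng.uniform(90, 100, len(genus)), 2))}
    return annotations, HostTable(genus=genus, confidence=confidence)


def write_fixture_files(seed: int, annotation_path, host_path) -> None:
    """Write the fixture tables as TSV/CSV (byte-identical per seed)."""
    annotations, hosts = simulate_fixtures(seed)
    annotations.to_csv(annotation_path, sep="\t", index=False)
    df = pd.DataFrame(
        {
            "Virus": list(hosts.genus),
            "Host taxonomy": [f"g__{g}" for g in hosts.genus.values()],
            "Confidence score": [hosts.confidence[p] for p in hosts.genus],
        }
    )
    df.to_csv(host_path, index=False)
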
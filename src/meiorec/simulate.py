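"""Synthetic meiotic octads and ChIP coverage tracks.

An *octad* is the set of 8 DNA strands recovered from one meiosis of a hybrid
diploid: each of the four spores performs one mitosis, the two daughter cells
are sequenced separately, and each daughter carries one of the two strands of
the spore's chromatid.  In a mismatch-repair-deficient (*msh2*Δ) hybrid the
heteroduplex DNA (hDNA) formed during recombination is not corrected, so a
marker inside an hDNA tract shows the two parental alleles on the two
daughters of the same spore (5:3 segregation over the octad).

The generator plants recombination events on an otherwise Mendelian 4:4
background (two spores per parental haplotype):

* **NCO** (non-crossover, SDSA outcome): a single gamma-length hDNA tract on
  one chromatid; one daughter strand carries the opposite parental allele
  over the tract.
* **CO** (crossover, DSBR outcome): a reciprocal exchange of flanking
  haplotypes between two non-sister chromatids at the event midpoint, plus an
  independent gamma-length hDNA tract on each involved chromatid abutting the
  midpoint on opposite sides (two-ended break-repair geometry).

Genotyping error (per-call allele flips) and missing calls are applied last.
Every planted event is recorded in a truth table so callers can be validated
by round-trip.

Coordinates are 1-based inclusive base pairs throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StageError

# genotype codes in the 8 x M call matrix
P1, P2, NA = 0, 1, -1
GENO_LABELS = {P1: "P1", P2: "P2", NA: "NA"}
STRAND_NAMES = ("s1a", "s1b", "s2a", "s2b", "s3a", "s3b", "s4a", "s4b")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic SNP map of one chromosome.

    ``allele_p1``/``allele_p2`` hold the parental alleles (distinct at every
    marker); ``positions`` are strictly increasing 1-based bp coordinates.
    """

    chrom: str
    positions: np.ndarray
    allele_p1: np.ndarray
    allele_p2: np.ndarray
    chrom_length: int

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size == 0:
            raise ParameterError("marker map must contain at least one marker")
        if np.any(np.diff(pos) <= 0):
            raise ParameterError("marker positions must be strictly increasing")
        if pos[0] < 1 or pos[-1] > self.chrom_length:
            raise ParameterError("marker positions must lie in [1, chrom_length]")
        if not (len(self.allele_p1) == len(self.allele_p2) == pos.size):
            raise ParameterError("allele vectors must match the number of positions")
        if np.any(np.asarray(self.allele_p1) == np.asarray(self.allele_p2)):
            raise ParameterError("parental alleles must differ at every marker")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class SimParams:
    """Parameters of one simulated meiosis (single chromosome).

    ``tract_mean``/``tract_shape`` parameterise the gamma law of hDNA tract
    lengths in bp (scale = mean/shape).  ``events_per_chrom`` is the Poisson
    mean of recombination events; ``p_co`` the per-event crossover
    probability.  ``geno_error`` flips individual strand calls, and
    ``missing_rate`` blanks them, both independently per call.
    """

    chrom_length: int = 200_000
    mean_marker_spacing: float = 160.0
    events_per_chrom: float = 3.0
    p_co: float = 0.5
    tract_mean: float = 1300.0
    tract_shape: float = 2.0
    min_event_sep: int = 10_000
    geno_error: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_co", "geno_error", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.tract_mean <= 0 or self.tract_shape <= 0:
            raise ParameterError("tract_mean and tract_shape must be positive")
        if self.min_event_sep < 0:
            raise ParameterError("min_event_sep must be non-negative")
        if self.events_per_chrom < 0:
            raise ParameterError("events_per_chrom must be non-negative")
        if self.chrom_length < 2 * self.mean_marker_spacing:
            raise ParameterError("chrom_length must be at least twice the marker spacing")


@dataclass(frozen=True)
class PlantedTract:
    """One planted hDNA interval on one spore (1-based inclusive bp)."""

    event_id: int
    event_type: str  # "CO" | "NCO"
    spore: int  # 0..3
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TruthTable:
    """All planted events of one simulated octad."""

    tracts: tuple[PlantedTract, ...]
    midpoints: tuple[float, ...]  # one per event id
    types: tuple[str, ...]
    co_spores: tuple[tuple[int, int] | None, ...]  # chromatid pair per CO event

    def __len__(self) -> int:
        return len(self.types)


@dataclass
class OctadGenotypes:
    """8 strands x M markers of parental-origin calls.

    Rows are ordered s1a, s1b, ..., s4b; rows ``2k`` and ``2k+1`` are the two
    daughter strands of spore ``k``.  Calls use the codes ``P1``/``P2``/``NA``.
    """

    map: MarkerMap
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (8, len(self.map)):
            raise ParameterError(
                f"call matrix must be 8 x {len(self.map)}, got {self.calls.shape}"
            )

    def spore_strands(self, spore: int) -> tuple[np.ndarray, np.ndarray]:
        return self.calls[2 * spore], self.calls[2 * spore + 1]


def make_marker_map(
    chrom_length: int,
    mean_spacing: float = 160.0,
    seed: int = 0,
    chrom: str = "chrI",
) -> MarkerMap:
    """Draw a dense biallelic marker map with geometric inter-marker gaps.

    Gaps are geometric with the stated mean (support >= 1 bp), emulating the
    roughly one-SNP-per-160-bp density of an S288C x SK1 hybrid.  Deterministic
    for a given seed.
    """
    if chrom_length <= 0 or mean_spacing <= 0:
        raise ParameterError("chrom_length and mean_spacing must be positive")
    if chrom_length < 2 * mean_spacing:
        raise ParameterError("chrom_length must be at least twice mean_spacing")
    rng = np.random.default_rng(seed)
    # oversample gaps, cumulate, truncate at the chromosome end
    n_guess = int(chrom_length / mean_spacing * 1.5) + 16
    positions: list[int] = []
    last = 0
    while True:
        gaps = rng.geometric(min(1.0, 1.0 / mean_spacing), size=n_guess)
        pos = last + np.cumsum(gaps)
        keep = pos <= chrom_length
        positions.extend(pos[keep].tolist())
        if not keep.all() or positions and positions[-1] >= chrom_length:
            break
        last = positions[-1] if positions else 0
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:  # pathological spacing >> length
        pos = np.asarray([chrom_length // 2], dtype=np.int64)
    idx1 = rng.integers(0, 4, size=pos.size)
    offset = rng.integers(1, 4, size=pos.size)
    allele_p1 = _BASES[idx1]
    allele_p2 = _BASES[(idx1 + offset) % 4]
    return MarkerMap(chrom, pos, allele_p1, allele_p2, int(chrom_length))


def _draw_event_midpoints(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_sep: float
) -> np.ndarray:
    """Draw n midpoints uniform over [lo, hi] given pairwise separation >= min_sep.

    Uses the direct construction (sorted uniforms in the interval shrunk by
    the total spacing, plus spacing offsets), which samples exactly the
    rejection-sampling distribution without ever failing on feasible inputs.
    """
    if n == 0:
        return np.empty(0)
    slack = (hi - lo) - (n - 1) * min_sep
    if hi <= lo or slack < 0:
        raise StageError(
            "simulate: cannot place events min_event_sep apart "
            "(lambda too high for the chromosome)"
        )
    mids = np.sort(rng.uniform(0.0, slack, size=n))
    return lo + mids + min_sep * np.arange(n)


def simulate_octad(marker_map: MarkerMap, params: SimParams) -> tuple[OctadGenotypes, TruthTable]:
    """Simulate one octad: plant events, then apply error and missingness.

    Spores 0 and 1 start as parent-1 haplotypes, spores 2 and 3 as parent-2,
    so every marker is 4:4 absent events.  Event midpoints are kept at least
    ``min_event_sep`` from the chromosome ends so planted tracts and their
    Mendelian flanks stay inside the map.
    """
    if len(marker_map) == 0:
        raise ParameterError("marker map is empty")
    rng = np.random.default_rng(params.seed)
    m = len(marker_map)
    calls = np.empty((8, m), dtype=np.int8)
    calls[0:4] = P1  # spores 0,1
    calls[4:8] = P2  # spores 2,3

    n_events = int(rng.poisson(params.events_per_chrom))
    margin = max(params.min_event_sep, 1)
    mids = _draw_event_midpoints(
        rng, n_events, margin, params.chrom_length - margin, params.min_event_sep
    )

    scale = params.tract_mean / params.tract_shape
    pos = marker_map.positions
    tracts: list[PlantedTract] = []
    types: list[str] = []
    co_spores: list[tuple[int, int] | None] = []

    # events are planted left to right; flank exchanges swap the *current*
    # chromatid contents and hDNA flips invert the current daughter calls, so
    # multiple events on one chromatid compose correctly
    for eid, mid in enumerate(mids):
        is_co = rng.random() < params.p_co
        if is_co:
            # exchange partners must differ in local background at the
            # midpoint, otherwise the crossover has no flanking-marker
            # footprint; every marker is 4:4 so two spores carry each parent
            k = int(np.searchsorted(pos, mid))
            k = min(k, len(pos) - 1)
            local = calls[::2, k]  # one daughter per spore, outside tracts
            p1_spores = np.flatnonzero(local == P1)
            p2_spores = np.flatnonzero(local == P2)
            sp_a = int(rng.choice(p1_spores))
            sp_b = int(rng.choice(p2_spores))
            right = pos > mid
            tmp = calls[2 * sp_a : 2 * sp_a + 2, right].copy()
            calls[2 * sp_a : 2 * sp_a + 2, right] = calls[2 * sp_b : 2 * sp_b + 2, right]
            calls[2 * sp_b : 2 * sp_b + 2, right] = tmp
            # one hDNA tract per involved chromatid, abutting the midpoint on
            # opposite sides (two-ended break-repair geometry)
            sides = ("left", "right") if rng.random() < 0.5 else ("right", "left")
            for spore, side in zip((sp_a, sp_b), sides):
                length = max(1, int(round(rng.gamma(params.tract_shape, scale))))
                if side == "left":
                    start, end = int(np.floor(mid)) - length + 1, int(np.floor(mid))
                else:
                    start, end = int(np.floor(mid)) + 1, int(np.floor(mid)) + length
                start = max(1, start)
                end = min(params.chrom_length, end)
                sel = (pos >= start) & (pos <= end)
                daughter = 2 * spore + int(rng.integers(0, 2))
                calls[daughter, sel] = 1 - calls[daughter, sel]
                tracts.append(PlantedTract(eid, "CO", spore, start, end))
            types.append("CO")
            co_spores.append((sp_a, sp_b))
        else:
            spore = int(rng.integers(0, 4))
            length = max(1, int(round(rng.gamma(params.tract_shape, scale))))
            start = max(1, int(np.floor(mid - length / 2)) + 1)
            end = min(params.chrom_length, start + length - 1)
            sel = (pos >= start) & (pos <= end)
            daughter = 2 * spore + int(rng.integers(0, 2))
            calls[daughter, sel] = 1 - calls[daughter, sel]
            tracts.append(PlantedTract(eid, "NCO", spore, start, end))
            types.append("NCO")
            co_spores.append(None)

    # genotyping noise, applied per strand-marker call, after event planting
    if params.geno_error > 0:
        flip = rng.random(calls.shape) < params.geno_error
        calls = np.where(flip, 1 - calls, calls).astype(np.int8)
    if params.missing_rate > 0:
        miss = rng.random(calls.shape) < params.missing_rate
        calls = np.where(miss, NA, calls).astype(np.int8)

    truth = TruthTable(tuple(tracts), tuple(float(x) for x in mids), tuple(types), tuple(co_spores))
    return OctadGenotypes(marker_map, calls), truth


@dataclass
class CoverageTrack:
    """Fixed-step genome signal vector with its normalization state.

    ``step`` is the bp per bin (1 = per-base).  ``state`` is one of ``raw``,
    ``mean_normalized``, ``subtracted`` or ``smoothed(w)``; the full history
    of transformations is kept in ``history``.
    """

    chrom: str
    values: np.ndarray
    step: int = 1
    state: str = "raw"
    history: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ParameterError("coverage values must be one-dimensional")
        if self.step < 1:
            raise ParameterError("step must be >= 1 bp")

    @property
    def genome_length(self) -> int:
        return int(self.values.size * self.step)

    def with_values(self, values: np.ndarray, state: str) -> "CoverageTrack":
        return CoverageTrack(
            self.chrom, values, self.step, state, self.history + (state,)
        )


@dataclass(frozen=True)
class Feature:
    """A genomic interval (0-based half-open) with an optional score."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ParameterError(f"invalid interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FeatureSet:
    """Named genomic intervals used as anchors or enrichment test sets."""

    features: list[Feature]
    kind: str = "feature"

    def __len__(self) -> int:
        return len(self.features)

    def midpoints(self) -> np.ndarray:
        return np.asarray([f.midpoint for f in self.features], dtype=np.int64)


def simulate_chip_tracks(
    genome_length: int,
    hotspots: FeatureSet,
    peak_sd: float = 500.0,
    background: float = 1.0,
    depth: float = 1.0,
    seed: int = 0,
    step: int = 1,
    chrom: str = "chrI",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Poisson-sampled signal/control pair with Gaussian peaks at hotspots.

    The signal rate is ``depth * (background + sum of Gaussian kernels)``, the
    control rate ``depth * background``; both tracks are integer counts per
    bin.  Doubling ``depth`` doubles expected totals.
    """
    if depth <= 0:
        raise ParameterError("depth must be positive")
    if background < 0 or peak_sd <= 0:
        raise ParameterError("background must be >= 0 and peak_sd > 0")
    n_bins = genome_length // step
    if n_bins < 1:
        raise ParameterError("genome_length shorter than one step")
    centers = (np.arange(n_bins) + 0.5) * step
    rate = np.full(n_bins, float(background))
    for f in hotspots.features:
        if not (0 <= f.midpoint <= genome_length):
            raise ParameterError(f"hotspot midpoint {f.midpoint} outside the genome")
        rate += f.score * np.exp(-0.5 * ((centers - f.midpoint) / peak_sd) ** 2)
    rng = np.random.default_rng(seed)
    signal = rng.poisson(depth * rate).astype(float)
    control = rng.poisson(depth * np.full(n_bins, float(background))).astype(float)
    return (
        CoverageTrack(chrom, signal, step, "raw", ("raw",)),
        CoverageTrack(chrom, control, step, "raw", ("raw",)),
    )
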
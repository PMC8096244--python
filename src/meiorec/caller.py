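"""Inference of hDNA tracts and CO/NCO events from 8-strand octad genotypes.

The octad exposes both strands of each spore's chromatid, so recombination
leaves two distinct footprints at a marker:

* **hDNA** — the two daughter strands of one spore disagree (5:3 segregation
  over the octad when mismatch repair is off);
* **full conversion** — both daughters carry the allele opposite to the
  spore's flanking haplotype background (6:2 segregation).

A *tract* is a maximal run of such non-Mendelian markers on one spore; tracts
from the chromatids of one recombination event are grouped by proximity, and
each event is classified CO (reciprocal exchange of flanking haplotypes
between two chromatids), NCO (no exchange), complex or unclassified.

Tract lengths are measured with the inter-marker midpoint convention: the
tract is taken to start halfway between the last Mendelian marker on the left
and the first converted marker, and to end halfway between the last converted
marker and the first Mendelian marker on the right; at a chromosome end the
terminal converted marker position itself is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError
from .simulate import NA, P1, P2, MarkerMap, OctadGenotypes

# per-marker, per-spore status codes
_MENDEL = 0
_HDNA = 1  # daughters discordant
_FULL = 2  # both daughters opposite to background
_MISSING = 3  # at least one daughter NA

SEGREGATION_CLASSES = ("4:4", "5:3", "3:5", "6:2", "2:6", "aberrant", "incomplete")


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the genotype caller and event grouper.

    ``min_purity`` is the allele fraction required to call a parental origin
    from read depths and ``min_depth`` the minimum total depth.  A tract may
    bridge at most ``merge_gap_markers`` interior Mendelian markers; tracts
    within ``event_merge_bp`` are grouped into one event; ``flank_k``
    Mendelian markers per side define the haplotype background used for
    CO/NCO classification; ``short_cutoff_bp`` is the short-tract threshold.
    """

    min_depth: int = 5
    min_purity: float = 0.9
    merge_gap_markers: int = 0
    event_merge_bp: int = 5000
    flank_k: int = 5
    short_cutoff_bp: int = 300

    def __post_init__(self) -> None:
        if not 0.5 < self.min_purity <= 1.0:
            raise ParameterError("min_purity must lie in (0.5, 1]")
        for name in ("min_depth", "merge_gap_markers", "event_merge_bp", "flank_k", "short_cutoff_bp"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class HDNATract:
    """A maximal non-Mendelian marker run on one spore, measured in bp."""

    spore: int
    chrom: str
    first_marker: int  # index of first converted marker
    last_marker: int  # index of last converted marker (inclusive)
    marker_indices: tuple[int, ...]  # converted markers only
    categories: tuple[str, ...]  # "hDNA" | "full", parallel to marker_indices
    start_bp: float
    end_bp: float
    low_confidence: bool = False
    event_id: int = -1

    @property
    def length_bp(self) -> float:
        return self.end_bp - self.start_bp

    @property
    def n_markers(self) -> int:
        return len(self.marker_indices)


@dataclass
class RecombEvent:
    """A group of tracts attributed to one recombination event."""

    event_id: int
    tracts: list[HDNATract]
    classification: str = "unclassified"  # CO | NCO | complex | unclassified
    chromatids: tuple[int, ...] = ()
    flanks: dict = field(default_factory=dict)  # spore -> (left_bg, right_bg)

    @property
    def span(self) -> tuple[float, float]:
        return (
            min(t.start_bp for t in self.tracts),
            max(t.end_bp for t in self.tracts),
        )


def call_genotypes(
    n_p1: np.ndarray,
    n_p2: np.ndarray,
    marker_map: MarkerMap,
    params: CallerParams = CallerParams(),
) -> OctadGenotypes:
    """Call parental origins from per-strand allele depths.

    A strand-marker is called P1 when the parent-1 fraction is at least
    ``min_purity`` and the total depth at least ``min_depth`` (P2 symmetric);
    anything else is NA.
    """
    n_p1 = np.asarray(n_p1, dtype=float)
    n_p2 = np.asarray(n_p2, dtype=float)
    if n_p1.shape != n_p2.shape:
        raise FormatError("allele-depth matrices differ in shape")
    if n_p1.shape != (8, len(marker_map)):
        raise FormatError(
            f"expected 8 strands x {len(marker_map)} markers, got {n_p1.shape}"
        )
    if (n_p1 < 0).any() or (n_p2 < 0).any():
        raise FormatError("allele depths must be non-negative")
    total = n_p1 + n_p2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac1 = np.where(total > 0, n_p1 / np.where(total > 0, total, 1), 0.0)
    calls = np.full(n_p1.shape, NA, dtype=np.int8)
    deep = total >= params.min_depth
    calls[deep & (frac1 >= params.min_purity)] = P1
    calls[deep & (1 - frac1 >= params.min_purity)] = P2
    return OctadGenotypes(marker_map, calls)


def classify_marker_segregation(octad: OctadGenotypes) -> pd.DataFrame:
    """Per-marker allele counts and segregation class over the 8 strands.

    Markers with any missing call are flagged ``incomplete`` and not
    classified further; complete markers fall into 4:4 / 5:3 / 3:5 / 6:2 /
    2:6 or ``aberrant`` (7:1, 8:0, ...).
    """
    calls = octad.calls
    n1 = (calls == P1).sum(axis=0)
    n2 = (calls == P2).sum(axis=0)
    nna = (calls == NA).sum(axis=0)
    cls = np.where(
        nna > 0,
        "incomplete",
        np.select(
            [
                (n1 == 4) & (n2 == 4),
                (n1 == 5) & (n2 == 3),
                (n1 == 3) & (n2 == 5),
                (n1 == 6) & (n2 == 2),
                (n1 == 2) & (n2 == 6),
            ],
            ["4:4", "5:3", "3:5", "6:2", "2:6"],
            default="aberrant",
        ),
    )
    return pd.DataFrame(
        {
            "pos": octad.map.positions,
            "n_p1": n1,
            "n_p2": n2,
            "n_na": nna,
            "class": cls,
        }
    )


def segment_strand(octad: OctadGenotypes, strand: int) -> list[tuple[int, int, int]]:
    """Runs of constant parental origin on one strand.

    Returns ``(allele, first_marker, last_marker)`` triples with 0-based
    inclusive marker indices.  NA calls never break a run: they are carried
    over into the enclosing or preceding run (leading NAs join the first
    run).  An all-NA strand yields an empty segmentation with a warning.
    """
    calls = octad.calls[strand]
    known = np.flatnonzero(calls != NA)
    if known.size == 0:
        warnings.warn(f"strand {strand} has no genotype calls", stacklevel=2)
        return []
    runs: list[tuple[int, int, int]] = []
    run_allele = int(calls[known[0]])
    run_start = 0  # leading NAs attach to the first run
    for idx in known[1:]:
        if calls[idx] != run_allele:
            runs.append((run_allele, run_start, int(idx) - 1))
            run_start = int(idx)
            run_allele = int(calls[idx])
    runs.append((run_allele, run_start, len(calls) - 1))
    return runs


def _spore_status(octad: OctadGenotypes, spore: int, flank_k: int) -> np.ndarray:
    """Per-marker status of one spore: Mendelian / hDNA / full / missing.

    The spore's haplotype background is anchored on maximal runs of at least
    ``flank_k`` consecutive concordant markers of one parental origin;
    between anchors of different origin (a crossover span) the left anchor
    wins, matching the left-flank rule used for event classification.
    """
    a, b = octad.spore_strands(spore)
    m = len(octad.map)
    status = np.full(m, _MENDEL, dtype=np.int8)
    missing = (a == NA) | (b == NA)
    discord = ~missing & (a != b)
    consensus = np.where(~missing & ~discord, a, NA).astype(np.int8)

    status[missing] = _MISSING
    status[discord] = _HDNA

    cons_idx = np.flatnonzero(consensus != NA)
    if cons_idx.size == 0:
        return status

    # maximal same-allele runs over the consensus subsequence
    alleles = consensus[cons_idx]
    breaks = np.flatnonzero(np.diff(alleles) != 0) + 1
    run_bounds = np.concatenate([[0], breaks, [alleles.size]])
    anchors: list[tuple[int, int, int]] = []  # (first_cons_pos, last_cons_pos, allele)
    for s, e in zip(run_bounds[:-1], run_bounds[1:]):
        if e - s >= flank_k:
            anchors.append((int(cons_idx[s]), int(cons_idx[e - 1]), int(alleles[s])))

    if not anchors:
        # tiny map: fall back to the global majority origin
        maj = P1 if (alleles == P1).sum() >= (alleles == P2).sum() else P2
        bg = np.full(m, maj, dtype=np.int8)
    else:
        bg = np.full(m, NA, dtype=np.int8)
        starts = np.array([a0 for a0, _, _ in anchors])
        ends = np.array([a1 for _, a1, _ in anchors])
        vals = np.array([al for _, _, al in anchors], dtype=np.int8)
        idx = np.arange(m)
        # left background: allele of the last anchor starting at or before m
        li = np.searchsorted(starts, idx, side="right") - 1
        left_bg = np.where(li >= 0, vals[np.clip(li, 0, None)], NA)
        # right background: allele of the first anchor ending at or after m
        ri = np.searchsorted(ends, idx, side="left")
        right_bg = np.where(ri < len(vals), vals[np.clip(ri, None, len(vals) - 1)], NA)
        bg = np.where(left_bg != NA, left_bg, right_bg).astype(np.int8)

    full = (consensus != NA) & (bg != NA) & (consensus != bg)
    status[full] = _FULL
    return status


def call_spore_tracts(
    octad: OctadGenotypes, params: CallerParams = CallerParams()
) -> list[HDNATract]:
    """Call all hDNA / conversion tracts of an octad, spore by spore.

    A marker is non-Mendelian for a spore when its daughters are discordant
    (hDNA) or when both carry the allele opposite to the spore's flanking
    background (full conversion).  Missing markers are neutral: they neither
    extend nor break a tract.  Isolated single-marker tracts whose immediate
    informative neighbours are both Mendelian are flagged low-confidence but
    retained.
    """
    tracts: list[HDNATract] = []
    pos = octad.map.positions
    for spore in range(4):
        status = _spore_status(octad, spore, params.flank_k)
        conv_idx = np.flatnonzero((status == _HDNA) | (status == _FULL))
        if conv_idx.size == 0:
            continue
        mendelian = status == _MENDEL
        # group converted markers, tolerating <= merge_gap_markers interior
        # Mendelian markers (missing markers are transparent)
        groups: list[list[int]] = [[int(conv_idx[0])]]
        for i in conv_idx[1:]:
            gap_mend = int(mendelian[groups[-1][-1] + 1 : i].sum())
            if gap_mend <= params.merge_gap_markers:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for grp in groups:
            first, last = grp[0], grp[-1]
            cats = tuple("hDNA" if status[i] == _HDNA else "full" for i in grp)
            start_bp, end_bp = tract_boundaries(first, last, octad.map, mendelian)
            left_inf = np.flatnonzero(status[:first] != _MISSING)
            right_inf = np.flatnonzero(status[last + 1 :] != _MISSING)
            lowconf = (
                len(grp) == 1
                and (left_inf.size == 0 or mendelian[left_inf[-1]])
                and (right_inf.size == 0 or mendelian[last + 1 + right_inf[0]])
                and left_inf.size > 0
                and right_inf.size > 0
            )
            tracts.append(
                HDNATract(
                    spore=spore,
                    chrom=octad.map.chrom,
                    first_marker=first,
                    last_marker=last,
                    marker_indices=tuple(grp),
                    categories=cats,
                    start_bp=start_bp,
                    end_bp=end_bp,
                    low_confidence=lowconf,
                )
            )
    return tracts


def tract_boundaries(
    first: int, last: int, marker_map: MarkerMap, mendelian: np.ndarray | None = None
) -> tuple[float, float]:
    """Tract start/end in bp by the inter-marker midpoint convention.

    ``mendelian`` marks the markers usable as flanks for this spore; when
    omitted, every marker outside the tract counts.  At a chromosome end the
    terminal converted marker position itself is the boundary.
    """
    pos = marker_map.positions
    if last < first:
        raise ParameterError("tract must contain at least one marker")
    if mendelian is None:
        mendelian = np.ones(len(marker_map), dtype=bool)
    left = np.flatnonzero(mendelian[:first])
    right = np.flatnonzero(mendelian[last + 1 :])
    start = (pos[left[-1]] + pos[first]) / 2 if left.size else float(pos[first])
    end = (pos[last] + pos[last + 1 + right[0]]) / 2 if right.size else float(pos[last])
    return float(start), float(end)


def measure_tract_length(tract: HDNATract) -> float:
    """Length in bp of a called tract (end minus start boundary)."""
    return tract.length_bp


def group_events(
    tracts: list[HDNATract], params: CallerParams = CallerParams()
) -> list[RecombEvent]:
    """Single-linkage grouping of tracts within ``event_merge_bp`` into events.

    Tracts (possibly on different chromatids) whose bp spans lie within the
    merge distance belong to one event; the two hDNA tracts flanking a
    crossover midpoint therefore coalesce.  Event ids are assigned in
    left-to-right order and written back onto the member tracts.
    """
    if not tracts:
        return []
    order = sorted(range(len(tracts)), key=lambda i: tracts[i].start_bp)
    events: list[RecombEvent] = []
    cur: list[HDNATract] = [tracts[order[0]]]
    cur_end = tracts[order[0]].end_bp
    for i in order[1:]:
        t = tracts[i]
        if t.start_bp - cur_end <= params.event_merge_bp:
            cur.append(t)
            cur_end = max(cur_end, t.end_bp)
        else:
            events.append(RecombEvent(len(events), cur))
            cur = [t]
            cur_end = t.end_bp
    events.append(RecombEvent(len(events), cur))
    for ev in events:
        ev.chromatids = tuple(sorted({t.spore for t in ev.tracts}))
        for t in ev.tracts:
            t.event_id = ev.event_id
    return events


def _flank_background(
    octad: OctadGenotypes, spore: int, lo: int, hi: int, flank_k: int
) -> tuple[int | None, int | None]:
    """Majority parental origin of the nearest flank_k concordant markers on
    each side of the marker window [lo, hi]."""
    a, b = octad.spore_strands(spore)
    concord = (a != NA) & (a == b)

    left_idx = np.flatnonzero(concord[:lo])[-flank_k:]
    right_idx = np.flatnonzero(concord[hi + 1 :])[:flank_k]
    left = None
    right = None
    if left_idx.size >= flank_k:
        vals = a[left_idx]
        left = P1 if (vals == P1).sum() > (vals == P2).sum() else P2
    if right_idx.size >= flank_k:
        vals = a[hi + 1 + right_idx]
        right = P1 if (vals == P1).sum() > (vals == P2).sum() else P2
    return left, right


def classify_event_co_nco(
    event: RecombEvent, octad: OctadGenotypes, params: CallerParams = CallerParams()
) -> str:
    """Classify one event as CO, NCO, complex or unclassified.

    For every spore the left/right haplotype backgrounds are the majority
    origin of the nearest ``flank_k`` concordant markers outside the event's
    marker span.  A CO requires two spores switching background in
    complementary directions (reciprocal exchange); an NCO requires that no
    spore switches; three or more switching chromatids make the event
    complex; anything else (insufficient flanks, lone switch) stays
    unclassified.
    """
    lo = min(t.first_marker for t in event.tracts)
    hi = max(t.last_marker for t in event.tracts)
    flanks: dict[int, tuple[int | None, int | None]] = {}
    for spore in range(4):
        flanks[spore] = _flank_background(octad, spore, lo, hi, params.flank_k)
    event.flanks = flanks

    converted_spores = {t.spore for t in event.tracts}
    if any(flanks[s][0] is None or flanks[s][1] is None for s in converted_spores):
        event.classification = "unclassified"
        return event.classification

    switches = {
        s: fl
        for s, fl in flanks.items()
        if fl[0] is not None and fl[1] is not None and fl[0] != fl[1]
    }
    if len(switches) >= 3:
        event.classification = "complex"
    elif any(
        switches[s] == (P1, P2) for s in switches
    ) and any(switches[s] == (P2, P1) for s in switches):
        event.classification = "CO"
        event.chromatids = tuple(sorted(set(event.chromatids) | set(switches)))
    elif not switches:
        event.classification = "NCO"
    else:
        event.classification = "unclassified"
    return event.classification


def call_octad(
    octad: OctadGenotypes, params: CallerParams = CallerParams()
) -> tuple[list[HDNATract], list[RecombEvent]]:
    """Full calling pipeline for one octad: tracts, events, classifications."""
    tracts = call_spore_tracts(octad, params)
    events = group_events(tracts, params)
    for ev in events:
        classify_event_co_nco(ev, octad, params)
    return tracts, events


def events_table(events: list[RecombEvent]) -> pd.DataFrame:
    """Flatten events into the tract-per-row table written by the CLI."""
    rows = []
    for ev in events:
        for t in ev.tracts:
            rows.append(
                {
                    "event_id": ev.event_id,
                    "class": ev.classification,
                    "spore": t.spore + 1,
                    "chrom": t.chrom,
                    "start_bp": t.start_bp,
                    "end_bp": t.end_bp,
                    "length_bp": t.length_bp,
                    "n_markers": t.n_markers,
                    "categories": ",".join(t.categories),
                    "flags": "low_confidence" if t.low_confidence else ".",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "class",
            "spore",
            "chrom",
            "start_bp",
            "end_bp",
            "length_bp",
            "n_markers",
            "categories",
            "flags",
        ],
    )
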
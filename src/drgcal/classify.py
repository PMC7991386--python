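"""Functional classification of colorectal afferents from response profiles.

Colorectal DRG neurons are probed with two mechanical stimuli: stepped
luminal distension (hydrostatic pressure steps of 15, 30, 45 and 60 mmHg,
5 s each — pressures from 30 mmHg up are noxious) and luminal shear flow
over the mucosa.  Which stimuli evoke calcium transients defines four
classes:

======================  ======================================  =========
class                   distension response                     shear
======================  ======================================  =========
low-threshold muscular  all four pressures                      no
high-threshold muscular noxious pressures only (≥ 30 mmHg)      no
mucosal                 none                                    yes
muscular-mucosal        all four pressures                      yes
======================  ======================================  =========

Profiles matching none of the four patterns are reported ``unclassified``
rather than coerced into the nearest class.  Neurons are grouped by the
ganglion housing the soma into the thoracolumbar (T12–L2, lumbar splanchnic
nerve) and lumbosacral (L5–S1, pelvic nerve) innervation pathways.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

DISTENSION_PRESSURES = (15, 30, 45, 60)  # mmHg
NOXIOUS_PRESSURES = (30, 45, 60)  # mmHg; ≥ 30 mmHg is noxious
TL_GANGLIA = frozenset({"T12", "T13", "L1", "L2"})
LS_GANGLIA = frozenset({"L5", "L6", "S1"})

_GANGLION_RE = re.compile(r"^[CTLS]\d{1,2}$")


@dataclass(frozen=True)
class DistensionStep:
    pressure: int  # mmHg, one of 15/30/45/60
    onset: float  # s
    duration: float = 5.0  # s

    def __post_init__(self) -> None:
        if self.pressure not in DISTENSION_PRESSURES:
            raise ValueError(f"pressure must be one of {DISTENSION_PRESSURES}, got {self.pressure}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ShearWindow:
    onset: float  # s
    duration: float  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class StimulusProtocol:
    """Timed mechanical stimulation windows for one recording."""

    distension_steps: list[DistensionStep] = field(default_factory=list)
    shear_windows: list[ShearWindow] = field(default_factory=list)
    flow_rate: float = 25.0  # mL/min, shear metadata

    def __post_init__(self) -> None:
        spans = [(s.onset, s.onset + s.duration) for s in self.distension_steps] + [
            (s.onset, s.onset + s.duration) for s in self.shear_windows
        ]
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError(f"stimulus windows overlap: [{a0}, {a1}) and [{b0}, {b1})")

    @property
    def first_onset(self) -> float | None:
        onsets = [s.onset for s in self.distension_steps] + [s.onset for s in self.shear_windows]
        return min(onsets) if onsets else None

    @property
    def end(self) -> float:
        spans = [s.onset + s.duration for s in self.distension_steps] + [
            s.onset + s.duration for s in self.shear_windows
        ]
        return max(spans) if spans else 0.0

    def to_dict(self) -> dict:
        return {
            "distension": [
                {"pressure_mmHg": s.pressure, "onset_s": s.onset, "duration_s": s.duration}
                for s in self.distension_steps
            ],
            "shear": [{"onset_s": s.onset, "duration_s": s.duration} for s in self.shear_windows],
            "flow_rate_mL_min": self.flow_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            distension_steps=[
                DistensionStep(int(s["pressure_mmHg"]), float(s["onset_s"]), float(s.get("duration_s", 5.0)))
                for s in d.get("distension", [])
            ],
            shear_windows=[
                ShearWindow(float(s["onset_s"]), float(s["duration_s"])) for s in d.get("shear", [])
            ],
            flow_rate=float(d.get("flow_rate_mL_min", 25.0)),
        )


@dataclass(frozen=True)
class ResponseProfile:
    """Boolean response flags per stimulus, derived from event timing."""

    neuron_id: int
    responded_15: bool = False
    responded_30: bool = False
    responded_45: bool = False
    responded_60: bool = False
    responded_shear: bool = False

    def responded(self, pressure: int) -> bool:
        return getattr(self, f"responded_{pressure}")

    @property
    def any_distension(self) -> bool:
        return any(self.responded(p) for p in DISTENSION_PRESSURES)

    @property
    def all_distension(self) -> bool:
        return all(self.responded(p) for p in DISTENSION_PRESSURES)


class AfferentClass(str, Enum):
    LT_MUSCULAR = "LT_muscular"
    HT_MUSCULAR = "HT_muscular"
    MUCOSAL = "mucosal"
    MUSCULAR_MUCOSAL = "muscular_mucosal"
    UNCLASSIFIED = "unclassified"


def build_profile(
    events,
    protocol: StimulusProtocol,
    neuron_id: int | None = None,
    latency: float = 1.0,
) -> ResponseProfile:
    """Co-register event peaks with stimulus windows.

    A stimulus flag is set iff at least one event peak falls inside
    ``[onset, offset + latency]``; the latency allowance (default 1 s,
    about one transient width) captures responses that peak just after the
    stimulus ends.
    """
    events = list(events)
    if neuron_id is None:
        neuron_id = events[0].neuron_id if events else -1
    peaks = [ev.peak_time for ev in events]

    def hit(onset: float, duration: float) -> bool:
        return any(onset <= t <= onset + duration + latency for t in peaks)

    flags = {f"responded_{p}": False for p in DISTENSION_PRESSURES}
    for step in protocol.distension_steps:
        if hit(step.onset, step.duration):
            flags[f"responded_{step.pressure}"] = True
    shear = any(hit(w.onset, w.duration) for w in protocol.shear_windows)
    return ResponseProfile(neuron_id=neuron_id, responded_shear=shear, **flags)


def classify_afferent(profile: ResponseProfile) -> AfferentClass:
    """Map a response profile onto the four-class taxonomy.

    The decision table is exact: responses at all four pressures without
    shear → LT muscular; responses confined to noxious pressures (none at
    15 mmHg, at least one at 30/45/60) without shear → HT muscular; shear
    only → mucosal; all four pressures plus shear → muscular-mucosal.  Any
    other combination is unclassified.
    """
    noxious_only = not profile.responded_15 and any(
        profile.responded(p) for p in NOXIOUS_PRESSURES
    )
    if profile.all_distension and not profile.responded_shear:
        return AfferentClass.LT_MUSCULAR
    if noxious_only and not profile.responded_shear:
        return AfferentClass.HT_MUSCULAR
    if profile.responded_shear and not profile.any_distension:
        return AfferentClass.MUCOSAL
    if profile.all_distension and profile.responded_shear:
        return AfferentClass.MUSCULAR_MUCOSAL
    return AfferentClass.UNCLASSIFIED


def pathway_of(ganglion: str) -> str:
    """Innervation pathway for a ganglion label (e.g. 'L6' → 'LS')."""
    g = ganglion.strip().upper()
    if not _GANGLION_RE.match(g):
        raise ValueError(f"unrecognized ganglion label: {ganglion!r}")
    if g in TL_GANGLIA:
        return "TL"
    if g in LS_GANGLIA:
        return "LS"
    return "other"


def class_summary(classes, ganglion_labels) -> pd.DataFrame:
    """Counts and proportions per class, overall and per pathway.

    Returns a tidy table with one row per (pathway, class) plus overall
    rows (pathway = 'all').  Proportions are within each pathway group.
    """
    classes = [AfferentClass(c) for c in classes]
    ganglia = list(ganglion_labels)
    if len(classes) != len(ganglia):
        raise ValueError("classes and ganglion_labels must have equal length")
    rows = []
    pathways = [pathway_of(g) for g in ganglia]
    df = pd.DataFrame({"afferent_class": [c.value for c in classes], "pathway": pathways})
    for group, sub in [("all", df)] + [(p, df[df.pathway == p]) for p in sorted(set(pathways))]:
        n = len(sub)
        for cls in AfferentClass:
            count = int((sub.afferent_class == cls.value).sum())
            rows.append(
                {
                    "pathway": group,
                    "afferent_class": cls.value,
                    "count": count,
                    "proportion": count / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
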
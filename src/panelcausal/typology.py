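"""Country-level causality typology.

Turns the six directional test outcomes (three variable pairs, two
directions each) into per-country direction labels, a three-way class
(bidirectional / unidirectional / none), the enumeration of distinct
label profiles, and rule-based dominant-source groupings.

Significance is assessed at ``alpha`` (default 0.10) with an inclusive
threshold (p <= alpha), matching the convention that a p-value printed as
exactly 0.050 or 0.100 is starred.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

__all__ = [
    "DirectionLabel",
    "CountryProfile",
    "TypologySummary",
    "label_directions",
    "classify_countries",
    "INTERPRETIVE_REGIMES",
]

LABELS = ("None", "A->B", "B->A", "Bidirectional")


@dataclass(frozen=True)
class DirectionLabel:
    pair: tuple[str, str]  # ordered (A, B)
    label: str  # one of LABELS

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"bad label {self.label!r}")


@dataclass(frozen=True)
class CountryProfile:
    unit_id: str
    labels: tuple[DirectionLabel, ...]  # one per pair, in pair order
    klass: str  # bidirectional | unidirectional | none
    dominant_group: str

    @property
    def profile_key(self) -> tuple[str, ...]:
        return tuple(l.label for l in self.labels)


@dataclass(frozen=True)
class TypologySummary:
    class_counts: dict[str, int]
    n_distinct_profiles: int
    profiles: dict[tuple[str, ...], list[str]]  # profile -> countries
    dominant_groups: dict[str, list[str]]


def label_directions(
    p_forward: float, p_reverse: float, alpha: float = 0.10
) -> str:
    """Four-way label for one ordered pair (A, B) from the two directional
    p-values (A->B, B->A); the threshold is inclusive (p <= alpha)."""
    f = p_forward <= alpha
    r = p_reverse <= alpha
    if f and r:
        return "Bidirectional"
    if f:
        return "A->B"
    if r:
        return "B->A"
    return "None"


def _edges(pair: tuple[str, str], label: str) -> list[tuple[str, str]]:
    a, b = pair
    return {
        "None": [],
        "A->B": [(a, b)],
        "B->A": [(b, a)],
        "Bidirectional": [(a, b), (b, a)],
    }[label]


def _dominant_group(
    klass: str, edges: list[tuple[str, str]], migr: str = "migr"
) -> str:
    """Rule-based dominant-source grouping.

    * any bidirectional pair -> 'feedback';
    * no edges -> 'none';
    * sources = {the two non-migration variables} and every edge targets the
      migration variable -> 'recipient';
    * a single source variable -> '<source>-dominant';
    * otherwise -> 'multi-linkage'.
    """
    if klass == "bidirectional":
        return "feedback"
    if not edges:
        return "none"
    sources = {s for s, _ in edges}
    targets = {t for _, t in edges}
    if len(sources) == 1:
        return f"{next(iter(sources))}-dominant"
    if targets == {migr} and migr not in sources:
        return "recipient"
    return "multi-linkage"


def classify_countries(
    p_values: dict[str, dict[tuple[str, str], float]],
    pairs: list[tuple[str, str]],
    alpha: float = 0.10,
    migration_variable: str = "migr",
) -> tuple[list[CountryProfile], TypologySummary]:
    """Classify every country from its six directional p-values.

    Parameters
    ----------
    p_values
        ``{unit: {(source, target): p}}`` with both directions present for
        every pair in ``pairs``.
    pairs
        Ordered variable pairs, e.g. ``[(co2, migr), (hexp, migr), (hexp, co2)]``.

    A country is *bidirectional* if at least one pair is labelled
    Bidirectional, *none* if all pair labels are None, else *unidirectional*.
    Distinct profiles are exact label-triple equalities.
    """
    profiles: list[CountryProfile] = []
    for unit in p_values:
        labels = []
        edges: list[tuple[str, str]] = []
        for a, b in pairs:
            try:
                pf = p_values[unit][(a, b)]
                pr = p_values[unit][(b, a)]
            except KeyError as exc:
                raise KeyError(f"missing direction {exc} for unit {unit!r}") from None
            lab = label_directions(pf, pr, alpha)
            labels.append(DirectionLabel((a, b), lab))
            edges.extend(_edges((a, b), lab))
        if any(l.label == "Bidirectional" for l in labels):
            klass = "bidirectional"
        elif all(l.label == "None" for l in labels):
            klass = "none"
        else:
            klass = "unidirectional"
        profiles.append(
            CountryProfile(
                unit, tuple(labels), klass,
                _dominant_group(klass, edges, migration_variable),
            )
        )

    counts = Counter(p.klass for p in profiles)
    prof_map: dict[tuple[str, ...], list[str]] = {}
    for p in profiles:
        prof_map.setdefault(p.profile_key, []).append(p.unit_id)
    groups: dict[str, list[str]] = {}
    for p in profiles:
        groups.setdefault(p.dominant_group, []).append(p.unit_id)
    summary = TypologySummary(
        class_counts={
            k: counts.get(k, 0) for k in ("bidirectional", "unidirectional", "none")
        },
        n_distinct_profiles=len(prof_map),
        profiles=prof_map,
        dominant_groups=groups,
    )
    return profiles, summary


# Optional interpretive mapping from rule-based groups to narrative regime
# labels. Interpretive only: the rule-based groups are the package's output.
INTERPRETIVE_REGIMES = {
    "feedback": "integrated nexus (feedback dynamics)",
    "co2-dominant": "environment-sensitive migration regime",
    "migr-dominant": "demographic-pressure-driven system",
    "recipient": "demographic-pressure-driven system",
    "hexp-dominant": "health-system-led regime",
    "multi-linkage": "multi-linkage (spans more than one regime)",
    "none": "structurally decoupled system",
}
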
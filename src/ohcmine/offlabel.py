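"""Off-label adjudication against the FDA-approved indication map.

A retained drug–indication pair is *off-label* when the indication
concept is not in the drug's approved set — unless the pair is negated,
in which case it is always flagged not off-label.  Matching is
concept-level: indication surfaces are first normalized through a
synonym table (the label map groups surface variants such as
"sleep disorder"/"insomnia" under one concept).

The approved-indication map for the 12 study drugs is bundled
(curated from the drugs' FDA labels via the openFDA
``indications_and_usage`` section) so the package runs offline;
:func:`fetch_label` is an optional online refresher.
"""

from __future__ import annotations

import json
import re
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .pairing import DrugIndicationPair

OPENFDA_LABEL_URL = "https://api.fda.gov/drug/label.json"


class LabelMapError(ValueError):
    """Malformed label map or an unadjudicable drug."""


@dataclass
class LabelMap:
    """drug concept -> set of approved indication concepts, plus a
    synonym table mapping indication surfaces to concepts."""

    approved: dict[str, frozenset[str]]
    synonyms: dict[str, str] = field(default_factory=dict)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        self.approved = {d.lower(): frozenset(v) for d, v in self.approved.items()}
        self.synonyms = {s.lower(): c for s, c in self.synonyms.items()}
        # every approved concept is at least its own synonym
        for concepts in self.approved.values():
            for c in concepts:
                self.synonyms.setdefault(c, c)

    @property
    def drugs(self) -> list[str]:
        return sorted(self.approved)

    def approved_for(self, drug: str) -> frozenset[str]:
        try:
            return self.approved[drug.lower()]
        except KeyError:
            raise LabelMapError(f"drug {drug!r} absent from label map") from None

    def is_approved(self, drug: str, indication_concept: str) -> bool:
        return indication_concept in self.approved_for(drug)


def load_label_map(path: str | Path | None = None) -> LabelMap:
    """Load a label map from JSON, or the bundled 12-drug default."""
    if path is None:
        from importlib import resources

        ref = resources.files("ohcmine") / "data" / "label_map.json"
        raw = json.loads(ref.read_text(encoding="utf-8"))
    else:
        with open(path, encoding="utf-8") as fh:
            try:
                raw = json.load(fh)
            except json.JSONDecodeError as exc:
                raise LabelMapError(f"malformed label map JSON: {exc}") from exc
    drugs = raw.get("drugs", raw if isinstance(raw, dict) and "drugs" not in raw else {})
    if not isinstance(drugs, dict):
        raise LabelMapError("label map 'drugs' must be an object")
    approved = {d: frozenset(v) for d, v in drugs.items()}
    return LabelMap(
        approved=approved,
        synonyms=dict(raw.get("synonyms", {})),
        version=str(raw.get("version", "unversioned")),
    )


_WS = re.compile(r"\s+")


def normalize_indication(surface: str, label_map: LabelMap) -> str:
    """Map an indication surface to its concept.

    Lowercases, trims and collapses whitespace, then looks the surface
    up in the synonym table.  Unknown surfaces map to themselves
    (whitespace replaced by underscores) as novel concepts.
    """
    key = _WS.sub(" ", surface.strip().lower())
    if key in label_map.synonyms:
        return label_map.synonyms[key]
    underscored = key.replace(" ", "_")
    return label_map.synonyms.get(underscored, underscored)


CONFIDENCE_LEVELS = ("high", "medium", "low")


def assign_confidence(pair: DrugIndicationPair, high_max_jumps: int = 4) -> str:
    """Confidence bucket for a retained pair.

    Same-sentence pairs with a short dependency path (<= ``high_max_jumps``)
    are *high*; longer same-sentence paths are *medium*; anything linked
    through the cross-sentence substitution rule is *low*.  The bucket
    boundaries are configurable — the underlying study reports buckets
    without defining them, so this scheme is a package convention.
    """
    if pair.substitution_used or not pair.same_sentence:
        return "low"
    return "high" if pair.jump_distance <= high_max_jumps else "medium"


@dataclass(frozen=True)
class OffLabelRecord:
    """One adjudicated drug–indication pair.

    Invariants: negated pairs and approved pairs are never off-label.
    """

    post_id: str
    drug: str
    indication: str
    off_label: bool
    confidence: str
    jump_distance: int
    same_sentence: bool
    substitution_used: bool
    negated: bool

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence {self.confidence!r}")
        if self.negated and self.off_label:
            raise ValueError("negated pairs must not be off-label")


def flag_off_label(
    pair: DrugIndicationPair, label_map: LabelMap, high_max_jumps: int = 4
) -> OffLabelRecord:
    """Adjudicate one retained pair against the approved-indication map.

    off_label = (not negated) AND (indication concept not approved for
    the drug).  Raises :class:`LabelMapError` for a drug the map cannot
    adjudicate.
    """
    drug = pair.drug.concept_id.lower()
    approved = label_map.approved_for(drug)  # raises for unknown drug
    concept = normalize_indication(pair.indication.concept_id, label_map)
    off = (not pair.negated) and (concept not in approved)
    return OffLabelRecord(
        post_id=pair.post_id,
        drug=drug,
        indication=concept,
        off_label=off,
        confidence=assign_confidence(pair, high_max_jumps=high_max_jumps),
        jump_distance=pair.jump_distance,
        same_sentence=pair.same_sentence,
        substitution_used=pair.substitution_used,
        negated=pair.negated,
    )


def fetch_label(
    drug_name: str,
    cache_dir: str | Path | None = None,
    offline: bool = False,
    timeout: float = 10.0,
) -> tuple[dict, list[str]]:
    """Fetch a drug's label from the openFDA API (optional, network).

    Returns the raw label JSON and the ``indications_and_usage``
    strings.  Responses are cached as JSON under ``cache_dir``; a
    cached response is used without touching the network.  With
    ``offline=True`` the call refuses unless a cached copy exists.
    """
    cache_file: Optional[Path] = None
    if cache_dir is not None:
        cache_file = Path(cache_dir) / f"openfda_{drug_name.lower()}.json"
        if cache_file.exists():
            raw = json.loads(cache_file.read_text(encoding="utf-8"))
            return raw, _indications_from_label(raw, drug_name)
    if offline:
        raise RuntimeError(
            f"offline mode: no cached openFDA label for {drug_name!r}; "
            "re-run with network access or provide a cache directory"
        )
    query = urllib.parse.urlencode(
        {"search": f'openfda.generic_name:"{drug_name}"', "limit": 1}
    )
    try:
        with urllib.request.urlopen(f"{OPENFDA_LABEL_URL}?{query}", timeout=timeout) as resp:
            raw = json.loads(resp.read().decode("utf-8"))
    except Exception as exc:  # pragma: no cover - network path
        raise RuntimeError(
            f"openFDA request for {drug_name!r} failed ({exc}); retry later "
            "or use the bundled label map"
        ) from exc
    indications = _indications_from_label(raw, drug_name)
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        cache_file.write_text(json.dumps(raw, indent=2), encoding="utf-8")
    return raw, indications


def _indications_from_label(raw: dict, drug_name: str) -> list[str]:
    results = raw.get("results", [])
    if not results:
        raise RuntimeError(f"no openFDA label found for {drug_name!r}")
    section = results[0].get("indications_and_usage")
    if not section:
        raise RuntimeError(f"label for {drug_name!r} has no indications_and_usage section")
    return list(section)
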
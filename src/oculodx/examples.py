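"""Bundled illustrative knowledge base and disease -> brain-zone map.

The shipped matrices (60 symptoms x 14 diseases, 60 x 8 brain zones) are an
ILLUSTRATIVE, NON-CLINICAL fixture: the linkage weights were chosen so that
each disease has a plausible, unique symptom profile that the interpretation
rules resolve, not curated from the clinical literature. They exist so the
scoring, interpretation, evaluation and simulation machinery can be run and
tested end to end; do not use them for patient care.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .knowledge_base import EntityKind, KnowledgeBase, load_knowledge_base

__all__ = [
    "load_example_disease_kb",
    "load_example_zone_kb",
    "load_example_zone_map",
]


def _read(name: str) -> str:
    return (resources.files("oculodx") / "data" / name).read_text(encoding="utf-8")


def load_example_disease_kb() -> KnowledgeBase:
    """The 60 x 14 illustrative disease matrix."""
    return load_knowledge_base(_read("example_disease_kb.tsv"), EntityKind.DISEASE)


def load_example_zone_kb() -> KnowledgeBase:
    """The 60 x 8 illustrative brain-zone matrix (same symptom catalog)."""
    return load_knowledge_base(_read("example_zone_kb.tsv"), EntityKind.BRAIN_ZONE)


def load_example_zone_map() -> dict[str, frozenset[str]]:
    """Disease -> set of affected brain zones used to label simulated patients."""
    raw = yaml.safe_load(_read("example_zone_map.yaml"))
    return {d: frozenset(zs) for d, zs in raw.items()}
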
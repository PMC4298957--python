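"""Access to the category schemes shipped with the package."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .categorizer import CategoryScheme, load_category_scheme
from .ontology import OntologyGraph


def _scheme_dir() -> Path:
    return Path(str(resources.files("gocat.data") / "schemes"))


def available_schemes() -> list[str]:
    """Names of the shipped schemes."""
    return sorted(p.stem for p in _scheme_dir().glob("*.tsv"))


def load_shipped_scheme(name: str, graph: OntologyGraph | None = None) -> CategoryScheme:
    """Load a shipped scheme by name (optionally validated against a graph)."""
    path = _scheme_dir() / f"{name}.tsv"
    if not path.exists():
        raise KeyError(
            f"no shipped scheme {name!r}; available: {available_schemes()}"
        )
    return load_category_scheme(path, graph=graph, name=name)
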
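"""Disease-name lexicon: canonical diseases and their keyword surface forms.

Past-medical-history notes rarely spell out a diagnosis in full. A record
such as ``"k/c/o DM since 5 yrs, HTN"`` names diabetes mellitus by its
abbreviation and hypertension likewise; other entries name a disease through
an associated clinical term ("Insulin", "FBS" for diabetes workup,
"Cholesterol" for coronary artery disease). The lexicon is the many-to-one
map from any of those surface forms to the canonical disease name, and it is
the sole vocabulary the tagger recognises — there is no fuzzy matching and
no spelling correction by design.

Matching is case-insensitive except for short all-uppercase abbreviations
(``DM``, ``HTN``, ``CAD``, ``RA``, ``FBS``, ``PPBS``, ``IDDM``): those match
only in uppercase, because "ra" or "dm" in lowercase running prose is almost
never a disease mention. Set ``strict_abbreviations=False`` to fold those
too, or ``case_sensitive=True`` for exact matching throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path

import yaml

__all__ = [
    "Lexicon",
    "LexiconError",
    "load_lexicon",
    "save_lexicon",
    "canonicalize",
    "default_lexicon",
]

#: Longest abbreviation length still treated as case-strict.
_ABBREV_MAX_LEN = 4


class LexiconError(ValueError):
    """Raised when a lexicon file or mapping violates the lexicon invariants."""


def _is_strict_abbreviation(keyword: str) -> bool:
    """All-uppercase keywords of <= 4 letters match only in uppercase."""
    return (
        len(keyword) <= _ABBREV_MAX_LEN
        and keyword.isalpha()
        and keyword.isupper()
    )


@dataclass(frozen=True)
class Lexicon:
    """Validated map from canonical disease names to keyword surface forms.

    Parameters
    ----------
    entries
        ``{canonical name: set of surface forms}``. Every keyword set must
        contain the canonical name itself, and no surface form (under the
        active case rule) may appear under two canonical names.
    case_sensitive
        If True, every lookup is exact-case.
    strict_abbreviations
        If True (default) short all-uppercase abbreviations are exact-case
        even when ``case_sensitive`` is False.
    """

    entries: dict[str, frozenset[str]]
    case_sensitive: bool = False
    strict_abbreviations: bool = True
    _lookup: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        frozen: dict[str, frozenset[str]] = {}
        for canonical, keywords in self.entries.items():
            if not canonical or not canonical.strip():
                raise LexiconError("canonical disease name must be non-empty")
            keyset = frozenset(keywords) | {canonical}
            for kw in keyset:
                if not kw or not kw.strip():
                    raise LexiconError(
                        f"empty keyword under canonical entry {canonical!r}"
                    )
                key = self._fold(kw)
                owner = lookup.get(key)
                if owner is not None and owner != canonical:
                    raise LexiconError(
                        f"keyword {kw!r} appears under both "
                        f"{owner!r} and {canonical!r}"
                    )
                lookup[key] = canonical
            frozen[canonical] = keyset
        object.__setattr__(self, "entries", frozen)
        object.__setattr__(self, "_lookup", lookup)

    def _fold(self, surface: str) -> str:
        if self.case_sensitive:
            return surface
        if self.strict_abbreviations and _is_strict_abbreviation(surface):
            return surface  # uppercase-only token keeps its case
        return surface.casefold()

    def canonical_for(self, surface: str) -> str | None:
        """Canonical disease whose keyword set contains ``surface``, or None."""
        exact = self._lookup.get(surface)
        if exact is not None:
            return exact
        if self.case_sensitive:
            return None
        # Strict-abbreviation keys are stored in their original (upper) case,
        # so a casefolded probe can only hit case-insensitive keywords.
        return self._lookup.get(surface.casefold())

    @property
    def keywords(self) -> frozenset[str]:
        """Every surface form in the lexicon."""
        return frozenset(kw for kws in self.entries.values() for kw in kws)

    def __contains__(self, surface: str) -> bool:
        return self.canonical_for(surface) is not None

    def __len__(self) -> int:
        return len(self.entries)


def default_lexicon(**kwargs: bool) -> Lexicon:
    """The built-in lexicon shipped with the package (``data/lexicon.yaml``)."""
    ref = importlib.resources.files("medhx") / "data" / "lexicon.yaml"
    return _from_mapping(yaml.safe_load(ref.read_text(encoding="utf-8")), **kwargs)


def _from_mapping(raw: object, **kwargs: bool) -> Lexicon:
    if not isinstance(raw, dict):
        raise LexiconError("lexicon file must be a mapping of canonical -> list")
    entries: dict[str, frozenset[str]] = {}
    for canonical, keywords in raw.items():
        if keywords is None:
            keywords = []
        if isinstance(keywords, str) or not isinstance(keywords, (list, tuple, set)):
            raise LexiconError(
                f"keywords for {canonical!r} must be a list, got {type(keywords).__name__}"
            )
        entries[str(canonical)] = frozenset(str(k) for k in keywords) | {str(canonical)}
    return Lexicon(entries=entries, **kwargs)


def load_lexicon(path: str | PathLike | None = None, **kwargs: bool) -> Lexicon:
    """Load a lexicon from a YAML/JSON mapping file, or the built-in default.

    The file maps each canonical disease name to a (possibly empty) list of
    additional keywords; the canonical name itself is always included as a
    surface form. Raises :class:`LexiconError` on duplicate or empty
    keywords.
    """
    if path is None:
        return default_lexicon(**kwargs)
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = yaml.safe_load(text)  # YAML superset also covers JSON
    except yaml.YAMLError as exc:
        raise LexiconError(f"could not parse lexicon file {path}: {exc}") from exc
    return _from_mapping(raw, **kwargs)


def save_lexicon(lex: Lexicon, path: str | PathLike) -> None:
    """Write ``lex`` in the flat file format read back by :func:`load_lexicon`."""
    out = {
        canonical: sorted(kw for kw in keywords if kw != canonical)
        for canonical, keywords in sorted(lex.entries.items())
    }
    Path(path).write_text(
        yaml.safe_dump(out, sort_keys=True, allow_unicode=True), encoding="utf-8"
    )


def canonicalize(surface: str, lex: Lexicon) -> str | None:
    """Map a surface form to its canonical disease name (None if unknown)."""
    return lex.canonical_for(surface)
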
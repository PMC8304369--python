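"""Bundled demonstration rule catalogue and profile metadata.

The full production catalogue covers over a hundred TAP families;
the bundled one covers the families whose rules exercise every code
path (vetoes, satellite families, coverage cutoffs) and is what the
fixture generator and the worked examples use. User-supplied
catalogues load through the same :func:`tapkit.rules.load_rules` /
:func:`tapkit.hmmio.parse_profile_metadata` machinery.
"""

from __future__ import annotations

from importlib import resources

from tapkit.hmmio import ProfileLibrary, parse_profile_metadata
from tapkit.rules import RuleSet, load_rules

__all__ = ["demo_rules", "demo_library"]


def _data_path(name: str):
    return resources.files("tapkit.data").joinpath(name)


def demo_rules(generation: str = "v3") -> RuleSet:
    """The bundled rule catalogue.

    ``generation="v3"`` includes the bZIPAUREO/bZIPCDD satellite
    families and the HMG_box vetoes on PHD, CCAAT_HAP5 and
    SWI/SNF_SNF2; ``generation="v2"`` is the older catalogue without
    them, kept for before/after comparisons of multi-domain protein
    assignment.
    """
    if generation not in ("v2", "v3"):
        raise ValueError(f"unknown rule generation {generation!r}")
    with resources.as_file(_data_path(f"demo_rules_{generation}.txt")) as p:
        return load_rules(p)


def demo_library() -> ProfileLibrary:
    """Profile metadata matching the bundled rule catalogue."""
    with resources.as_file(_data_path("demo_profiles.tsv")) as p:
        return parse_profile_metadata(p)
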
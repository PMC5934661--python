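"""Workflow presets: which scoring systems enter the integrated score.

Two workflows exist for known variants (K11 with all systems, K10 without
fitCons, whose purely evolutionary signal weakens the ensemble on clinical
variants) and two for novel variants (N8 drops the three GWAVA classifiers,
which only score catalogued SNPs; N6 additionally drops CADD and DeepSEA,
which discriminate recurrent somatic mutations poorly).
"""

from __future__ import annotations

from .io import DEFAULT_SYSTEM_SPECS, ValidationError

_ALL = tuple(s.id for s in DEFAULT_SYSTEM_SPECS)
_GWAVA = tuple(s.id for s in DEFAULT_SYSTEM_SPECS if s.known_only)

WORKFLOWS: dict[str, tuple[str, ...]] = {
    "K11": _ALL,
    "K10": tuple(s for s in _ALL if s != "fitcons"),
    "N8": tuple(s for s in _ALL if s not in _GWAVA),
    "N6": tuple(s for s in _ALL if s not in _GWAVA + ("cadd", "deepsea")),
}


def workflow_systems(workflow_id: str) -> tuple[str, ...]:
    """Active system ids for a workflow preset, in canonical order."""
    try:
        return WORKFLOWS[workflow_id]
    except KeyError:
        raise ValidationError(
            f"unknown workflow {workflow_id!r}; choose one of {', '.join(WORKFLOWS)}"
        ) from None
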
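"""Delta-notation reference scales and conversions between them.

A δ⁴⁴/⁴²Ca value is always expressed relative to a named reference standard.
The in-house bracketing standard defines the ``WIGL`` scale; community scales
(ICP Ca Lyon, ICP1, NIST SRM 915a) differ from it by fixed additive offsets,
so conversion between any two registered scales is the difference of their
offsets — exact and invertible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

#: Canonical scale names.
WIGL = "WIGL"
ICP_CA_LYON = "ICP_Ca_Lyon"
ICP1 = "ICP1"
SRM915A = "SRM915a"

_DEFAULT_OFFSETS = {
    WIGL: 0.0,
    ICP_CA_LYON: 0.009,
    ICP1: 0.277,
    SRM915A: 0.527,
}

# accept a few spelling variants on input
_ALIASES = {
    "wigl": WIGL,
    "icp_ca_lyon": ICP_CA_LYON,
    "icp ca lyon": ICP_CA_LYON,
    "lyon": ICP_CA_LYON,
    "icp1": ICP1,
    "srm915a": SRM915A,
    "srm 915a": SRM915A,
    "nist srm 915a": SRM915A,
}


@dataclass(frozen=True)
class ScaleRegistry:
    """Registry of additive per-mille offsets from the in-house (WIGL) scale."""

    offsets: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_OFFSETS))

    def resolve(self, name: str) -> str:
        key = _ALIASES.get(str(name).strip().lower())
        if key is None or key not in self.offsets:
            if name in self.offsets:
                return name
            raise ConfigError(
                f"unknown reference scale {name!r}; registered scales: "
                f"{sorted(self.offsets)}"
            )
        return key

    def offset(self, name: str) -> float:
        return self.offsets[self.resolve(name)]


DEFAULT_REGISTRY = ScaleRegistry()


def convert_scale(
    value: float,
    from_scale: str,
    to_scale: str,
    registry: ScaleRegistry = DEFAULT_REGISTRY,
) -> float:
    """Convert a per-mille delta value between two registered reference scales.

    ``result = value + (offset[to] - offset[from])`` where ``offset[s]`` is the
    per-mille shift added when re-expressing a WIGL-scale delta on scale ``s``:
    a sample at 0‰ on the in-house scale reads +0.527‰ on the SRM 915a scale.
    """
    return value + registry.offset(to_scale) - registry.offset(from_scale)
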
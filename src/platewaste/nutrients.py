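"""Nutrient vectors: the currency of the nutrition stage.

A :class:`NutrientProfile` is an immutable, non-negative vector over the fixed
component list :data:`COMPONENTS` (energy plus macro- and micronutrients).
Profiles support element-wise addition, subtraction (floored at zero with a
:class:`~platewaste.errors.DataQualityWarning` when a component would go
negative) and scaling by a non-negative scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .errors import ValidationError, DataQualityWarning

#: Canonical component order.  Every profile, composition row and guideline
#: quantity refers to these names.
COMPONENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "carbohydrate_g",
    "soluble_sugars_g",
    "fat_g",
    "cholesterol_mg",
    "fibre_g",
    "vit_a_ug",
    "vit_b1_mg",
    "vit_b2_mg",
    "vit_b3_mg",
    "vit_b6_mg",
    "vit_b9_ug",
    "vit_b12_ug",
    "vit_c_mg",
    "vit_d_ug",
    "na_mg",
    "k_mg",
    "ca_mg",
    "p_mg",
    "fe_mg",
    "zn_mg",
    "cu_mg",
)

#: Unit string for each component, used to validate guideline bound rows.
COMPONENT_UNITS: dict[str, str] = {
    name: name.rsplit("_", 1)[1] for name in COMPONENTS
}

_INDEX: dict[str, int] = {name: i for i, name in enumerate(COMPONENTS)}


@dataclass(frozen=True, eq=False)
class NutrientProfile:
    """Immutable non-negative nutrient vector aligned with :data:`COMPONENTS`."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(len(COMPONENTS)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientProfile):
            return NotImplemented
        return bool(np.array_equal(self.values, other.values))

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (len(COMPONENTS),):
            raise ValidationError(
                f"profile must have {len(COMPONENTS)} components, got shape {arr.shape}"
            )
        if np.any(arr < 0):
            bad = [COMPONENTS[i] for i in np.flatnonzero(arr < 0)]
            raise ValidationError(f"negative nutrient components: {bad}")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    # -- constructors ------------------------------------------------------
    @classmethod
    def zeros(cls) -> "NutrientProfile":
        return cls(np.zeros(len(COMPONENTS)))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "NutrientProfile":
        """Build a profile from a name -> value mapping.

        Missing components default to zero; unknown names raise.
        """
        arr = np.zeros(len(COMPONENTS))
        for name, value in mapping.items():
            if name not in _INDEX:
                raise ValidationError(f"unknown nutrient component {name!r}")
            arr[_INDEX[name]] = float(value)
        return cls(arr)

    # -- element access ----------------------------------------------------
    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[_INDEX[name]])
        except KeyError:
            raise KeyError(f"unknown nutrient component {name!r}") from None

    def to_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(COMPONENTS, self.values)}

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "NutrientProfile") -> "NutrientProfile":
        if not isinstance(other, NutrientProfile):
            return NotImplemented
        return NutrientProfile(self.values + other.values)

    def __sub__(self, other: "NutrientProfile") -> "NutrientProfile":
        """Element-wise difference floored at zero.

        Warns (once per call) when any component would go negative; use
        :meth:`diff` for the exact signed difference.
        """
        if not isinstance(other, NutrientProfile):
            return NotImplemented
        raw = self.values - other.values
        if np.any(raw < 0):
            bad = [COMPONENTS[i] for i in np.flatnonzero(raw < 0)]
            warnings.warn(
                f"nutrient subtraction floored at 0 for components {bad}",
                DataQualityWarning,
                stacklevel=2,
            )
        return NutrientProfile(np.maximum(raw, 0.0))

    def diff(self, other: "NutrientProfile") -> np.ndarray:
        """Exact (possibly negative) component-wise difference, as an array."""
        return self.values - other.values

    def __mul__(self, scalar: float) -> "NutrientProfile":
        scalar = float(scalar)
        if scalar < 0:
            raise ValidationError("profiles cannot be scaled by a negative factor")
        return NutrientProfile(self.values * scalar)

    __rmul__ = __mul__

    def isclose(self, other: "NutrientProfile", rtol: float = 1e-9, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, other.values, rtol=rtol, atol=atol))
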
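"""Binding constants, kinetic rate pairs, and thermodynamic-cycle closure.

The model is parameterized entirely by pairwise dissociation constants
(``kd``, μM).  Association rates are not individually measured; every
binding step is assigned a common diffusion-limited on-rate
(``kon_default``, μM⁻¹ s⁻¹) and the off-rate follows from ``koff = kon·kd``.
Where the binding network contains a closed cycle (C + M + H can assemble
into the ternary CMH along two paths), one edge must be *derived* from the
others so that the product of equilibrium constants around the cycle is
exactly one (detailed balance); otherwise the "equilibrium" of the ODE
system would sustain a perpetual cyclic flux.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "BindingConstant",
    "RatePair",
    "ParameterSet",
    "CensoredConstantError",
    "close_cycle",
    "rates_for",
    "default_parameter_set",
    "load_parameter_set",
]

#: Diffusion-limited bimolecular association rate, μM⁻¹·s⁻¹ (1e7 M⁻¹s⁻¹).
KON_DIFFUSION_LIMIT = 10.0

#: Derived cycle edges: pair_id -> (kd_a, kd_b, kd_c) with kd = kd_a·kd_b/kd_c.
#: The C + MH ⇌ CMH edge closes the M/MH/CM/CMH thermodynamic square.
CYCLE_RULES: dict[str, tuple[str, str, str]] = {
    "C-MH": ("C-M", "CM-H", "M-H"),
}


class CensoredConstantError(ValueError):
    """Raised when a lower-bound-only constant is used as a point estimate."""


@dataclass(frozen=True)
class BindingConstant:
    """A pairwise dissociation constant.

    Parameters
    ----------
    pair_id : str
        Ordered label pair joined by ``-`` (e.g. ``"C-M"``).
    kd : float
        Dissociation constant in μM; must be positive.
    censored : bool
        True when only a lower bound is known (e.g. "Kd > 10 mM"); censored
        entries are excluded from kinetic use unless explicitly overridden.
    source : str
        Free-text provenance tag.
    derived : bool
        True when the value was produced by detailed-balance cycle closure
        rather than measured.
    """

    pair_id: str
    kd: float
    censored: bool = False
    source: str = ""
    derived: bool = False

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError(f"kd must be positive, got {self.kd} for {self.pair_id}")

    @property
    def partners(self) -> tuple[str, str]:
        a, b = self.pair_id.split("-")
        return a, b


@dataclass(frozen=True)
class RatePair:
    """Mass-action rate constants realizing a dissociation constant."""

    kon: float  # μM⁻¹·s⁻¹
    koff: float  # s⁻¹

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0):
            raise ValueError("kon and koff must be positive")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


def close_cycle(kd_cm: float, kd_h_given_cm: float, kd_h_given_m: float) -> float:
    """Detailed-balance closure of the four-state binding square.

    For the square M ⇌ MH, M ⇌ CM, CM ⇌ CMH, MH ⇌ CMH, given the
    dissociation constants for C+M (``kd_cm``), for H binding the CM complex
    (``kd_h_given_cm``) and for H binding free M (``kd_h_given_m``), returns
    the unique Kd for C binding MH such that the product of equilibrium
    constants around the cycle equals one.
    """
    for name, v in (("kd_cm", kd_cm), ("kd_h_given_cm", kd_h_given_cm),
                    ("kd_h_given_m", kd_h_given_m)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return kd_cm * kd_h_given_cm / kd_h_given_m


def rates_for(constant: BindingConstant, kon_default: float) -> RatePair:
    """Convert a Kd into (kon, koff) under the diffusion-limit assumption."""
    if constant.censored:
        raise CensoredConstantError(
            f"{constant.pair_id} is a lower bound (kd > {constant.kd} μM), "
            "not a point estimate; it cannot be converted to kinetic rates"
        )
    if not kon_default > 0:
        raise ValueError("kon_default must be positive")
    return RatePair(kon=kon_default, koff=kon_default * constant.kd)


@dataclass(frozen=True)
class ParameterSet:
    """Named species plus measured and cycle-derived binding constants."""

    constants: Mapping[str, BindingConstant]
    kon_default: float = KON_DIFFUSION_LIMIT
    species: tuple[str, ...] = ("M", "H", "C", "R")

    def __post_init__(self) -> None:
        if not self.kon_default > 0:
            raise ValueError("kon_default must be positive")

    # -- access -----------------------------------------------------------

    def __contains__(self, pair_id: str) -> bool:
        return pair_id in self.constants

    def get(self, pair_id: str) -> BindingConstant:
        try:
            return self.constants[pair_id]
        except KeyError:
            raise KeyError(f"missing constant {pair_id}") from None

    def kd(self, pair_id: str) -> float:
        return self.get(pair_id).kd

    def rates(self, pair_id: str) -> RatePair:
        return rates_for(self.get(pair_id), self.kon_default)

    @property
    def derived_ids(self) -> frozenset[str]:
        return frozenset(k for k, c in self.constants.items() if c.derived)

    # -- modification -----------------------------------------------------

    def with_override(self, pair_id: str, kd: float) -> "ParameterSet":
        """Return a copy with one measured constant replaced.

        Cycle-derived edges are recomputed; overriding a derived edge
        directly is refused because it would break detailed balance.
        """
        cur = self.get(pair_id)
        if cur.derived:
            raise ValueError(
                f"{pair_id} is derived by detailed-balance cycle closure and "
                "cannot be set directly; override one of its source edges"
            )
        consts = dict(self.constants)
        consts[pair_id] = replace(cur, kd=kd, censored=False)
        return ParameterSet(
            constants=_with_derived(consts), kon_default=self.kon_default,
            species=self.species,
        )

    # -- validation -------------------------------------------------------

    def check_cycles(self, rtol: float = 1e-9) -> None:
        """Verify every derived edge satisfies its cycle identity."""
        for pair_id, (a, b, c) in CYCLE_RULES.items():
            if pair_id not in self.constants:
                continue
            expect = close_cycle(self.kd(a), self.kd(b), self.kd(c))
            got = self.kd(pair_id)
            if not math.isclose(got, expect, rel_tol=rtol):
                raise ValueError(
                    f"cycle closure violated for {pair_id}: {got} != {expect}"
                )

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": list(self.species),
            "kon_default": self.kon_default,
            "constants": [
                {
                    "pair": list(c.partners),
                    "kd_uM": c.kd,
                    "censored": c.censored,
                    "source": c.source,
                }
                for c in self.constants.values()
                if not c.derived
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        consts: dict[str, BindingConstant] = {}
        for entry in data["constants"]:
            a, b = entry["pair"]
            pair_id = f"{a}-{b}"
            if pair_id in consts:
                raise ValueError(f"duplicate constant {pair_id}")
            consts[pair_id] = BindingConstant(
                pair_id=pair_id,
                kd=float(entry["kd_uM"]),
                censored=bool(entry.get("censored", False)),
                source=str(entry.get("source", "")),
            )
        return cls(
            constants=_with_derived(consts),
            kon_default=float(data.get("kon_default", KON_DIFFUSION_LIMIT)),
            species=tuple(data.get("species", ("M", "H", "C", "R"))),
        )

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _with_derived(consts: dict[str, BindingConstant]) -> dict[str, BindingConstant]:
    """Append cycle-closed derived edges where their source edges exist."""
    out = {k: v for k, v in consts.items() if not v.derived}
    for pair_id, (a, b, c) in CYCLE_RULES.items():
        if all(e in out and not out[e].censored for e in (a, b, c)):
            out[pair_id] = BindingConstant(
                pair_id=pair_id,
                kd=close_cycle(out[a].kd, out[b].kd, out[c].kd),
                source=f"detailed balance: {a}·{b}/{c}",
                derived=True,
            )
    return out


def load_parameter_set(path) -> ParameterSet:
    """Read a parameter file (YAML mapping, see packaged default)."""
    return ParameterSet.from_yaml(path)


def default_parameter_set() -> ParameterSet:
    """The packaged set of measured constants for the switch network."""
    ref = resources.files("cyp33switch.data") / "default_parameters.yaml"
    with resources.as_file(ref) as path:
        return ParameterSet.from_yaml(path)
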
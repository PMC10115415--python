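"""Mass-action reaction network of the chromatin switch.

Species (default network): the MLL1 PHD3-BRD reader module M, the H3K4me3
tail H, Cyp33 C, a single-site RNA R, and the complexes MH, CM, CMH, CR and
RH.  RNA is treated as one binding site bound exclusively by either Cyp33 or
the H3K4me3 tail — no C·R·H ternary — and the Cyp33 RRM/PHD3 interface
occludes the RNA surface, so CR binds neither M nor H.

The module provides the ODE right-hand side, a closed-form 1:1 bound-fraction
oracle, and an algebraic equilibrium solver (damped fixed-point iteration on
free monomer concentrations with a root-finder fallback).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .parameters import ParameterSet, RatePair

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "EquilibrationError",
    "build_network",
    "ode_rhs",
    "bound_fraction_1to1",
    "equilibrate",
    "integrate",
]

#: monomer composition of the default complex species
DEFAULT_COMPOSITIONS: dict[str, dict[str, int]] = {
    "MH": {"M": 1, "H": 1},
    "CM": {"C": 1, "M": 1},
    "CMH": {"C": 1, "M": 1, "H": 1},
    "CR": {"C": 1, "R": 1},
    "RH": {"R": 1, "H": 1},
}

#: default reversible reaction list: (reactants, product, pair_id of the Kd)
DEFAULT_REACTIONS: list[tuple[tuple[str, str], str, str]] = [
    (("M", "H"), "MH", "M-H"),
    (("C", "M"), "CM", "C-M"),
    (("CM", "H"), "CMH", "CM-H"),
    (("C", "R"), "CR", "C-R"),
    (("R", "H"), "RH", "R-H"),
    (("C", "MH"), "CMH", "C-MH"),
]

NEG_TOL = 1e-9  # μM; most-negative concentration tolerated from the solver


class EquilibrationError(RuntimeError):
    """Equilibrium solver failed to converge; carries the residual."""

    def __init__(self, msg: str, residual: float):
        super().__init__(f"{msg} (residual {residual:.3e})")
        self.residual = residual


@dataclass(frozen=True)
class Reaction:
    """A reversible association: reactants ⇌ product."""

    reactants: tuple[str, ...]
    product: str
    kon: float  # μM⁻¹·s⁻¹
    koff: float  # s⁻¹
    pair_id: str = ""

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0):
            raise ValueError(f"rates must be positive for {self.pair_id}")

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]          # lexicographic order, deterministic
    monomers: tuple[str, ...]
    compositions: Mapping[str, Mapping[str, int]]  # species -> monomer counts
    reactions: tuple[Reaction, ...]

    @property
    def stoichiometry(self) -> np.ndarray:
        """Species × reactions matrix for the forward (association) direction."""
        S = np.zeros((len(self.species), len(self.reactions)))
        idx = self.index
        for j, rxn in enumerate(self.reactions):
            for r in rxn.reactants:
                S[idx[r], j] -= 1
            S[idx[rxn.product], j] += 1
        return S

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    @property
    def conservation_groups(self) -> dict[str, list[tuple[str, int]]]:
        """For each monomer, the species containing it with multiplicity."""
        groups: dict[str, list[tuple[str, int]]] = {m: [] for m in self.monomers}
        for s in self.species:
            for m, mult in self.compositions[s].items():
                groups[m].append((s, mult))
        return groups

    def conservation_matrix(self) -> np.ndarray:
        """Monomers × species matrix of multiplicities."""
        A = np.zeros((len(self.monomers), len(self.species)))
        idx = self.index
        for i, m in enumerate(self.monomers):
            for s, mult in self.conservation_groups[m]:
                A[i, idx[s]] = mult
        return A

    def totals(self, state: np.ndarray) -> dict[str, float]:
        A = self.conservation_matrix()
        vals = A @ np.asarray(state, dtype=float)
        return dict(zip(self.monomers, vals))

    def rates(self, y: np.ndarray) -> np.ndarray:
        """Net forward flux per reaction (μM/s) at concentrations ``y``."""
        idx = self.index
        v = np.empty(len(self.reactions))
        for j, rxn in enumerate(self.reactions):
            fwd = rxn.kon
            for r in rxn.reactants:
                fwd *= y[idx[r]]
            v[j] = fwd - rxn.koff * y[idx[rxn.product]]
        return v


def build_network(params: ParameterSet,
                  reactions: Sequence[tuple[tuple[str, str], str, str]] | None = None,
                  compositions: Mapping[str, Mapping[str, int]] | None = None,
                  ) -> ReactionNetwork:
    """Assemble the reversible mass-action network from a parameter set.

    With defaults this is the six-reaction, nine-species switch network
    (five measured edges plus the detailed-balance-derived C+MH ⇌ CMH edge).
    Missing or censored constants raise with the offending pair named.
    """
    rxn_list = list(DEFAULT_REACTIONS if reactions is None else reactions)
    comps = dict(DEFAULT_COMPOSITIONS if compositions is None else compositions)

    monomers: set[str] = set()
    species: set[str] = set()
    rxns: list[Reaction] = []
    for reactants, product, pair_id in rxn_list:
        rp: RatePair = params.rates(pair_id)  # raises on missing/censored
        rxns.append(Reaction(reactants=tuple(reactants), product=product,
                             kon=rp.kon, koff=rp.koff, pair_id=pair_id))
        species.update(reactants)
        species.add(product)
    for s in species:
        if s in comps:
            continue
        comps[s] = {s: 1}
        monomers.add(s)
    # sanity: composition must be conserved across each reaction
    for rxn in rxns:
        lhs: Counter = Counter()
        for r in rxn.reactants:
            lhs.update(comps[r])
        if lhs != Counter(comps[rxn.product]):
            raise ValueError(f"composition not conserved in {rxn.pair_id}")

    ordered = tuple(sorted(species))
    return ReactionNetwork(
        species=ordered,
        monomers=tuple(sorted(monomers)),
        compositions={s: dict(comps[s]) for s in ordered},
        reactions=tuple(rxns),
    )


def ode_rhs(network: ReactionNetwork, y: np.ndarray) -> np.ndarray:
    """Mass-action time derivatives (μM/s) for the given state."""
    y = np.asarray(y, dtype=float)
    if y.shape != (len(network.species),):
        raise ValueError("state length does not match network species")
    if np.any(y < -NEG_TOL):
        raise ValueError(f"negative concentration beyond {NEG_TOL} μM")
    return network.stoichiometry @ network.rates(np.maximum(y, 0.0))


def bound_fraction_1to1(p_total: float, l_total: float, kd: float) -> float:
    """Fraction of P in complex for a single 1:1 equilibrium (closed form).

    [PL] = ((P+L+Kd) − sqrt((P+L+Kd)² − 4·P·L)) / 2.  Returns 0 for P=0.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if p_total < 0 or l_total < 0:
        raise ValueError("totals must be non-negative")
    if p_total == 0:
        return 0.0
    s = p_total + l_total + kd
    disc = s * s - 4.0 * p_total * l_total
    pl = (s - np.sqrt(max(disc, 0.0))) / 2.0
    return float(pl / p_total)


# ---------------------------------------------------------------------------
# equilibrium solver
# ---------------------------------------------------------------------------

def _betas(network: ReactionNetwork) -> dict[str, float]:
    """Overall association constant of each species relative to free monomers.

    β(monomer)=1; β(complex)=∏ free-monomer powers coefficient such that
    [X]_eq = β_X · ∏ [m]^ν.  Propagated through the reaction list; a cycle
    that assigns two inconsistent values means detailed balance is broken.
    """
    beta: dict[str, float] = {m: 1.0 for m in network.monomers}
    pending = list(network.reactions)
    progress = True
    while pending and progress:
        progress = False
        rest = []
        for rxn in pending:
            if all(r in beta for r in rxn.reactants):
                val = rxn.kon / rxn.koff
                for r in rxn.reactants:
                    val *= beta[r]
                if rxn.product in beta:
                    if not np.isclose(val, beta[rxn.product], rtol=1e-9):
                        raise ValueError(
                            f"detailed balance violated at {rxn.pair_id}: "
                            f"β={val} vs {beta[rxn.product]}"
                        )
                else:
                    beta[rxn.product] = val
                progress = True
            else:
                rest.append(rxn)
        pending = rest
    if pending:
        raise ValueError("species unreachable from monomers")
    return beta


def equilibrate(network: ReactionNetwork, totals: Mapping[str, float],
                max_iter: int = 100_000, damping: float = 0.5,
                flux_tol: float = 1e-9) -> np.ndarray:
    """Algebraic equilibrium state for given per-monomer totals (μM).

    Damped multiplicative fixed-point iteration on the free monomer
    concentrations, falling back to a dense root-finder on the log of the
    free concentrations.  The returned state satisfies every reaction's net
    flux < ``flux_tol`` μM/s and reproduces the totals to 1e-6 relative.
    """
    tot = np.array([float(totals.get(m, 0.0)) for m in network.monomers])
    if np.any(tot < 0):
        raise ValueError("totals must be non-negative")
    beta = _betas(network)
    active = tot > 0
    mono = [m for m, a in zip(network.monomers, active) if a]
    t = tot[active]

    state = np.zeros(len(network.species))
    idx = network.index
    if mono:
        # complexes composed only of active monomers
        comps = [s for s in network.species
                 if s not in network.monomers
                 and all(m in mono for m in network.compositions[s])]
        nu = np.array([[network.compositions[s].get(m, 0) for m in mono]
                       for s in comps])  # n_comps × n_mono
        b = np.array([beta[s] for s in comps])

        def bound(f: np.ndarray) -> np.ndarray:
            """Per-monomer amount sequestered in complexes at free concs f."""
            if not comps:
                return np.zeros_like(f)
            cc = b * np.prod(f ** nu, axis=1)
            return cc @ nu

        f = t.copy()  # start from all-free
        converged = False
        for _ in range(max_iter):
            g = f + bound(f)
            ratio = t / g
            f_new = f * ratio ** damping
            if np.max(np.abs(np.log(ratio))) < 1e-14:
                f = f_new
                converged = True
                break
            f = f_new
        if not converged:
            sol = root(lambda x: np.log((np.exp(x) + bound(np.exp(x))) / t),
                       np.log(f), method="hybr", tol=1e-14)
            f = np.exp(sol.x)
            resid = float(np.max(np.abs(f + bound(f) - t)))
            if not sol.success and resid > 1e-8:
                raise EquilibrationError("equilibrium solver failed", resid)
        for m, fv in zip(mono, f):
            state[idx[m]] = fv
        for s, bb, row in zip(comps, b, nu):
            state[idx[s]] = bb * np.prod(f ** row)

    # flux scales as concentration², so the check is referenced to the
    # 100 μM working scale to stay meaningful in double precision
    scale = max(1.0, (np.max(tot, initial=0.0) / 100.0) ** 2)
    flux = network.rates(state)
    if np.max(np.abs(flux), initial=0.0) > flux_tol * scale:
        raise EquilibrationError("nonzero net flux at solution",
                                 float(np.max(np.abs(flux))))
    return state


def integrate(network: ReactionNetwork, y0: np.ndarray, t_span: tuple[float, float],
              t_eval: np.ndarray | None = None, extra_rhs=None,
              rtol: float = 1e-8, atol: float = 1e-10):
    """Stiff integration of the network ODEs (optionally with extra terms).

    ``extra_rhs(t, y)`` adds open-system terms (synthesis/decay) to the
    mass-action derivatives.  Off-rates span ~0.05–3000 s⁻¹, so an implicit
    stiff method (LSODA) is used.
    """
    S = network.stoichiometry

    def rhs(t, y):
        dy = S @ network.rates(np.maximum(y, 0.0))
        if extra_rhs is not None:
            dy = dy + extra_rhs(t, y)
        return dy

    sol = solve_ivp(rhs, t_span, y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1]:.3f}s: {sol.message}")
    if np.min(sol.y) < -NEG_TOL:
        raise RuntimeError(f"negative concentration {np.min(sol.y):.2e} during integration")
    return sol.t, np.maximum(sol.y.T, 0.0)
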
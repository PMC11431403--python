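"""Built-in parameter regimes.

The presets span the qualitative transfer regimes of the dimer: the exact
TET degeneracy, its neighbourhood (small positive reaction energy and a tiny
seed transfer integral, which makes zero-temperature transfer irreversible),
the two Marcus regimes of activated transfer, and a strongly unbalanced
"away" regime where the ionic coupling dominates by a factor 25 in
``k^2/Omega^2``.  Dampings default to 0.1, in the crossover between the
underdamped regime (long-lived donor-acceptor oscillation) and the
overdamped regime (transfer slowed by friction).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import DimerParams

__all__ = ["RegimePreset", "PRESETS", "get_preset", "preset_names"]


@dataclass(frozen=True)
class RegimePreset:
    """A named parameter regime with a one-line description."""

    name: str
    params: DimerParams
    description: str


_DEFAULT_GAMMA = 0.1

PRESETS: dict[str, RegimePreset] = {
    "tet": RegimePreset(
        name="tet",
        params=DimerParams(E_D=0.0, E_A=0.0, k_z=1.0, k_x=1.0, eps_x=0.0,
                           Omega_z=1.0, Omega_x=1.0,
                           gamma_z=_DEFAULT_GAMMA, gamma_x=_DEFAULT_GAMMA),
        description=("Pure symmetric TET degeneracy: resonant on-site levels, "
                     "balanced ionic/covalent couplings, vanishing bare transfer "
                     "integral; the PES has a cylindrically symmetric conical "
                     "intersection with a flat circular reaction path."),
    ),
    "near_tet": RegimePreset(
        name="near_tet",
        params=DimerParams(E_D=0.5, E_A=0.0, k_z=1.0, k_x=1.0, eps_x=-0.001,
                           Omega_z=1.0, Omega_x=1.0,
                           gamma_z=_DEFAULT_GAMMA, gamma_x=_DEFAULT_GAMMA),
        description=("Near-TET: balanced couplings with a small positive "
                     "reaction energy E_D - E_A = 0.5 and a seed transfer "
                     "integral eps_x = -0.001; transfer is downhill along the "
                     "degenerate groove and irreversible at zero temperature."),
    ),
    "marcus_normal": RegimePreset(
        name="marcus_normal",
        params=DimerParams(E_D=0.5, E_A=0.0, k_z=2.0, k_x=0.1, eps_x=-0.02,
                           Omega_z=1.0, Omega_x=1.0,
                           gamma_z=_DEFAULT_GAMMA, gamma_x=_DEFAULT_GAMMA),
        description=("Marcus normal regime: ionic coupling dominates, the "
                     "diabatic parabolas cross between their minima (driving "
                     "force below the reorganisation energy) and transfer is "
                     "thermally activated over a barrier."),
    ),
    "marcus_inverted": RegimePreset(
        name="marcus_inverted",
        params=DimerParams(E_D=3.0, E_A=0.0, k_z=1.0, k_x=0.1, eps_x=-0.02,
                           Omega_z=1.0, Omega_x=1.0,
                           gamma_z=_DEFAULT_GAMMA, gamma_x=_DEFAULT_GAMMA),
        description=("Marcus inverted regime: the driving force E_D - E_A "
                     "exceeds the reorganisation energy, so the diabatic "
                     "crossing lies outside the inter-minimum interval and "
                     "larger exothermicity raises the activation energy."),
    ),
    "away": RegimePreset(
        name="away",
        params=DimerParams(E_D=0.5, E_A=0.0, k_z=2.5, k_x=0.5, eps_x=-0.1,
                           Omega_z=1.0, Omega_x=1.0,
                           gamma_z=_DEFAULT_GAMMA, gamma_x=_DEFAULT_GAMMA),
        description=("Far from TET: the ionic/covalent balance is broken by a "
                     "factor 25 in k^2/Omega^2, leaving an activation barrier "
                     "of a few energy units; the adiabatic gap closes only on "
                     "the line u_x = -eps_x/k_x, transfer is blocked at zero "
                     "temperature and follows Arrhenius kinetics around "
                     "kBT ~ 1."),
    ),
}


def preset_names() -> list[str]:
    return list(PRESETS)


def get_preset(name: str) -> RegimePreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}"
        ) from None
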
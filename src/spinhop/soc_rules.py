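"""Qualitative SOC-magnitude classifier from one-center selection rules.

For molecules with a heavy main-group atom (iodine in the motivating
systems), the Slater-Condon rules applied to a one-center effective
spin-orbit Hamiltonian say that SOC between a singlet and a triplet can
only be large when the two states differ in a *single* pair of molecular
orbitals, each carrying a strong admixture of a *different* (hence
mutually perpendicular) valence p atomic orbital of the *same* heavy
atom.  The classical El-Sayed rules are the special case of this
statement for (n,pi*) vs (pi,pi*) pairs.

The classifier maps a pair of excited-state characters to one of four
magnitude categories anchored at the printed ranges:

    units            ~ 1-9 cm^-1     (e.g. (pi,pi*) vs (pi,pi*))
    tens             ~ 10-99 cm^-1   (e.g. closed shell vs (n,pi*))
    hundreds_to_2000 ~ 100-2000 cm^-1 (perpendicular heavy-p pair)
    atomic_like_2300 ~ 2300 cm^-1    (closed shell vs (n,sigma*): both MOs
                                      essentially atomic p of the heavy atom)

It is a transparent rule table with human-readable rationales, intended
for fixture design and report annotation; it computes no integrals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = ["StateCharacter", "SOCCategory", "classify_pair", "CHARACTER_LABELS"]

CHARACTER_LABELS = (
    "ground_closed_shell",
    "pi_pi_star",
    "n_pi_star",
    "pi_sigma_star",
    "n_sigma_star",
)

# (hole, particle) occupation difference of each character vs the closed shell
_EXCITATION = {
    "ground_closed_shell": None,
    "pi_pi_star": ("pi", "pi*"),
    "n_pi_star": ("n", "pi*"),
    "pi_sigma_star": ("pi", "sigma*"),
    "n_sigma_star": ("n", "sigma*"),
}

# heavy-atom p character of each orbital type at a planar geometry:
# (has strong p admixture by default, orientation key, essentially atomic)
# 'n' is the in-plane lone pair, 'sigma*' the C-heavy antibond (in plane,
# along the bond, perpendicular to the lone pair), 'pi' may carry the
# out-of-plane p, 'pi*' is a ring orbital with at best weak admixture.
_ORBITAL_P = {
    "n": (True, "in_plane_lone", True),
    "sigma*": (True, "in_plane_bond", True),
    "pi": (False, "out_of_plane", False),   # admixture off unless flagged
    "pi*": (False, None, False),
}


@dataclass(frozen=True)
class StateCharacter:
    """Excitation character plus heavy-atom p admixture bookkeeping.

    ``source_heavy_p``/``target_heavy_p`` flag a strong heavy-atom p
    admixture of the orbital the electron leaves/enters; the orientation
    tag ("in_plane" | "out_of_plane") is only meaningful with the flag
    set.  ``same_heavy_atom`` states that the key orbitals of the pair
    under comparison sit on one and the same heavy atom.
    """

    character: str
    source_heavy_p: bool = False
    source_orientation: Optional[str] = None
    target_heavy_p: bool = False
    target_orientation: Optional[str] = None
    same_heavy_atom: bool = True

    def __post_init__(self):
        if self.character not in _EXCITATION:
            raise ValueError(f"unknown character {self.character!r}")

    def orbital_p(self, orbital: str, role: str) -> Tuple[bool, Optional[str]]:
        """(has heavy p, orientation) of one of this state's orbitals."""
        has, orient, _atomic = _ORBITAL_P[orbital]
        flag = self.source_heavy_p if role == "hole" else self.target_heavy_p
        override = (
            self.source_orientation if role == "hole" else self.target_orientation
        )
        if orbital == "pi":
            has = flag       # pi only counts as heavy-p-bearing when flagged
        if override is not None:
            orient = {"in_plane": "in_plane_lone", "out_of_plane": "out_of_plane"}[
                override
            ]
        return has, orient


@dataclass(frozen=True)
class SOCCategory:
    label: str
    representative_range_cm1: Tuple[float, float]
    rationale: str


_RANGES = {
    "units": (1.0, 9.0),
    "tens": (10.0, 99.0),
    "hundreds_to_2000": (100.0, 2000.0),
    "atomic_like_2300": (2300.0, 2300.0),
}


def _category(label: str, rationale: str) -> SOCCategory:
    return SOCCategory(label=label, representative_range_cm1=_RANGES[label],
                       rationale=rationale)


def _differing_pair(a: StateCharacter, b: StateCharacter):
    """The single MO pair the two states differ in, or None if 0 or >= 2.

    Returns (orbital_x, owner_state_x, role_x, orbital_y, owner_state_y,
    role_y) or the strings "identical" / "multiple".
    """
    ea, eb = _EXCITATION[a.character], _EXCITATION[b.character]
    if ea == eb:
        return "identical"
    if ea is None or eb is None:
        exc, owner = (eb, b) if ea is None else (ea, a)
        return (exc[0], owner, "hole", exc[1], owner, "particle")
    (h1, p1), (h2, p2) = ea, eb
    if h1 == h2 and p1 != p2:
        return (p1, a, "particle", p2, b, "particle")
    if p1 == p2 and h1 != h2:
        return (h1, a, "hole", h2, b, "hole")
    return "multiple"


def classify_pair(a: StateCharacter, b: StateCharacter) -> SOCCategory:
    """Qualitative SOC magnitude category for a singlet/triplet pair.

    Deterministic and symmetric in its arguments.  The caller is
    responsible for the spin bookkeeping (one state of the pair is
    singlet-type, the other triplet-type).
    """
    pair = _differing_pair(a, b)
    if pair == "identical":
        return _category(
            "units",
            "nearly identical orbital occupations: SOC between virtually "
            "isoenergetic same-configuration states is suppressed",
        )
    if pair == "multiple":
        return _category(
            "units",
            "the states differ in two or more MO pairs: one-center "
            "one-electron SOC cannot connect them",
        )
    orb_x, own_x, role_x, orb_y, own_y, role_y = pair
    has_x, ori_x = own_x.orbital_p(orb_x, role_x)
    has_y, ori_y = own_y.orbital_p(orb_y, role_y)
    same_atom = a.same_heavy_atom and b.same_heavy_atom

    if has_x and has_y and same_atom:
        if ori_x == ori_y:
            return _category(
                "units",
                f"the differing MOs ({orb_x}, {orb_y}) carry the *same* "
                "heavy-atom p orbital: no one-center SOC",
            )
        _, _, atomic_x = _ORBITAL_P[orb_x]
        _, _, atomic_y = _ORBITAL_P[orb_y]
        if atomic_x and atomic_y:
            return _category(
                "atomic_like_2300",
                f"{orb_x} and {orb_y} are both essentially atomic p orbitals "
                "of the heavy atom with perpendicular orientations: "
                "atomic-like SOC",
            )
        return _category(
            "hundreds_to_2000",
            f"single differing MO pair ({orb_x}, {orb_y}), each with strong "
            "admixture of a different (perpendicular) heavy-atom p: large SOC",
        )
    if has_x or has_y:
        return _category(
            "tens",
            f"only one of the differing MOs ({orb_x}, {orb_y}) carries "
            "heavy-atom p character"
            + ("" if same_atom else " (or the key orbitals sit on different atoms)")
            + ": moderate, text-derived",
        )
    return _category(
        "units",
        f"neither differing MO ({orb_x}, {orb_y}) has appreciable "
        "heavy-atom p admixture: small SOC",
    )
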
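"""Adduct/ion mass arithmetic for electrospray ionization.

All masses are monoisotopic, in Da (Th for singly charged ions).  The
adduct sets are the ones used both for drug-ion exclusion and for m/z
compound annotation:

positive mode: [M+H]+, [M+Na]+, [M+K]+
negative mode: [M-H]-, [M+Na-2H]-, [M+K-2H]-

The bare sodium/potassium adducts are not observable as negative ions, so
the charge-consistent [M+Na-2H]-/[M+K-2H]- forms are used there.  Drug-ion
expansion additionally appends the first 13C isotopologue of every ion.
"""

from __future__ import annotations

POSITIVE = "positive"
NEGATIVE = "negative"
MODES = (POSITIVE, NEGATIVE)

#: mass of a proton (H minus electron), Da
PROTON = 1.007276
#: mass shift of the first 13C isotopologue, Da
C13_SHIFT = 1.003355

#: per-mode adduct label -> neutral-mass shift (Da) for singly charged ions
ADDUCT_SHIFTS: dict[str, dict[str, float]] = {
    POSITIVE: {
        "[M+H]+": PROTON,
        "[M+Na]+": 22.989218,
        "[M+K]+": 38.963158,
    },
    NEGATIVE: {
        "[M-H]-": -PROTON,
        "[M+Na-2H]-": 20.974666,
        "[M+K-2H]-": 36.948606,
    },
}


def check_mode(mode: str) -> str:
    if mode not in MODES:
        raise ValueError(f"unknown ionization mode {mode!r}; expected one of {MODES}")
    return mode


def adduct_mz(neutral_mass: float, mode: str, isotopologues: bool = False) -> list[tuple[str, float]]:
    """Expand a neutral monoisotopic mass into its singly charged ions.

    Parameters
    ----------
    neutral_mass:
        Neutral monoisotopic mass in Da; must be positive.
    mode:
        ``"positive"`` or ``"negative"``.
    isotopologues:
        If true, append the first 13C isotopologue of every adduct ion
        (label suffixed with ``" 13C"``).

    Returns
    -------
    list of ``(label, mz)`` pairs.
    """
    check_mode(mode)
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    ions = [(label, neutral_mass + shift) for label, shift in ADDUCT_SHIFTS[mode].items()]
    if isotopologues:
        ions += [(f"{label} 13C", mz + C13_SHIFT) for label, mz in list(ions)]
    return ions
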
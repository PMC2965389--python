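"""Hairpin folding free energies from a nearest-neighbor model.

Terminator hairpins are scored with a Turner-style nearest-neighbor model:
stacking free energies for consecutive base pairs (Watson-Crick and GU wobble;
values after Xia et al. 1998 Biochemistry 37:14719 for WC/WC steps and the
Turner 2004 compilation for wobble-containing steps), a hairpin-loop
initiation penalty by loop size (3-30 nt; larger loops use the size-30 value),
and a +0.45 kcal/mol penalty when the terminal (outermost) pair is AU or GU.

Sequences are DNA-alphabet but scored as their RNA transcripts (T == U).
All energies are ΔG°37 in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["EnergyModel", "hairpin_delta_g", "PAIRS_WC", "PAIRS_GU", "pairs_allowed"]

PAIRS_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
PAIRS_GU = {("G", "T"), ("T", "G")}


def pairs_allowed(allow_gu: bool = True) -> set[tuple[str, str]]:
    return PAIRS_WC | PAIRS_GU if allow_gu else set(PAIRS_WC)


# Stack step (p1, p2): pair p1 = (top, bottom) followed 5'->3' on the top
# strand by pair p2.  21 unique steps; the rest follow from the physical
# symmetry (p1, p2) == (reverse(p2), reverse(p1)).  DNA letters, T == U.
_UNIQUE_STACKS: dict[tuple[str, str], float] = {
    # Watson-Crick / Watson-Crick (Xia et al. 1998)
    ("AT", "AT"): -0.93,
    ("AT", "TA"): -1.10,
    ("TA", "AT"): -1.33,
    ("CG", "TA"): -2.08,
    ("CG", "AT"): -2.11,
    ("GC", "TA"): -2.24,
    ("GC", "AT"): -2.35,
    ("CG", "GC"): -2.36,
    ("GC", "GC"): -3.26,
    ("GC", "CG"): -3.42,
    # steps with one or two GU wobbles (Turner 2004 compilation)
    ("AT", "GT"): -0.55,
    ("AT", "TG"): -1.36,
    ("TA", "GT"): -1.00,
    ("TA", "TG"): -1.27,
    ("CG", "GT"): -1.41,
    ("CG", "TG"): -2.11,
    ("GC", "GT"): -1.53,
    ("GC", "TG"): -2.51,
    ("GT", "GT"): -0.50,
    ("GT", "TG"): +0.47,
    ("TG", "GT"): +0.30,
}

# Hairpin loop initiation, sizes 3..30 (Turner 2004).
_HAIRPIN_LOOP = [
    5.40, 5.60, 5.70, 5.40, 6.00, 5.50, 6.40, 6.50, 6.60, 6.70, 6.78, 6.86,
    6.94, 7.01, 7.07, 7.13, 7.19, 7.25, 7.30, 7.35, 7.40, 7.44, 7.49, 7.53,
    7.57, 7.61, 7.65, 7.69,
]

_TERMINAL_AU = 0.45


def _expand_stacks() -> dict[tuple[str, str], float]:
    full: dict[tuple[str, str], float] = {}
    for (p1, p2), dg in _UNIQUE_STACKS.items():
        full[(p1, p2)] = dg
        sym = (p2[::-1], p1[::-1])
        if sym in full and abs(full[sym] - dg) > 1e-9:
            raise AssertionError(f"inconsistent stack symmetry for {p1}/{p2}")
        full[sym] = dg
    return full


@dataclass
class EnergyModel:
    stack_dg: dict[tuple[str, str], float] = field(default_factory=_expand_stacks)
    hairpin_loop_dg: dict[int, float] = field(
        default_factory=lambda: {i + 3: v for i, v in enumerate(_HAIRPIN_LOOP)}
    )
    terminal_au_penalty: float = _TERMINAL_AU

    def loop_penalty(self, loop_len: int) -> float:
        if loop_len < 3:
            raise ValueError(f"hairpin loop of {loop_len} nt is sterically impossible")
        return self.hairpin_loop_dg[min(loop_len, 30)]


_DEFAULT_MODEL: EnergyModel | None = None


def default_energy_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = EnergyModel()
    return _DEFAULT_MODEL


def hairpin_delta_g(
    stem5_seq: str,
    stem3_seq: str,
    loop_len: int,
    model: EnergyModel | None = None,
    allow_gu: bool = True,
) -> float:
    """ΔG°37 of a hairpin whose arms are ``stem5_seq`` (5'->3') and
    ``stem3_seq`` (5'->3'); position k of the 5' arm pairs with position
    len-1-k of the 3' arm.  Sum of stack terms over consecutive pairs, plus
    the loop initiation penalty, plus the terminal AU/GU penalty when the
    outermost pair is not GC/CG.
    """
    model = model or default_energy_model()
    s = len(stem5_seq)
    if s != len(stem3_seq) or s < 1:
        raise ValueError("stem arms must have equal length >= 1")
    allowed = pairs_allowed(allow_gu)
    pairs: list[str] = []
    for k in range(s):
        a, b = stem5_seq[k], stem3_seq[s - 1 - k]
        if (a, b) not in allowed:
            raise ValueError(f"arms do not pair at stem position {k}: {a}-{b}")
        pairs.append(a + b)
    dg = model.loop_penalty(loop_len)
    for k in range(s - 1):
        dg += model.stack_dg[(pairs[k], pairs[k + 1])]
    if pairs[0] not in ("GC", "CG"):
        dg += model.terminal_au_penalty
    return dg
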
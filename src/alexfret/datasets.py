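"""Published loss-of-FRET condition summaries (mean ± s.d., n = 3).

These are the printed per-condition statistics from the single-molecule
FACT / nucleosome reorganization study this package reanalyzes: the
percentage of bursts below the universal E* = 0.4 cutoff, averaged over three
independent experiments.  ``CORE_CONDITIONS`` is the four-condition family
establishing that only the complete yFACT assembly (FACT + Nhp6) reorganizes
nucleosomes; ``TRUNCATION_CONDITIONS`` is the seven-condition FACT-truncation
family (S = Spt16, P = Pob3, ΔN/ΔC = N-/C-terminal deletion) mapping which
domains the activity requires.
"""

from __future__ import annotations

from .groupstats import ConditionSummary, summary_condition

#: condition name -> (mean loss-of-FRET %, sample s.d.), n = 3 each
CORE_CONDITIONS: dict[str, tuple[float, float]] = {
    "nucleosome": (9.23, 2.20),
    "Nhp6": (10.96, 1.15),
    "FACT": (10.47, 3.01),
    "yFACT": (72.12, 0.46),
}

TRUNCATION_CONDITIONS: dict[str, tuple[float, float]] = {
    "yFACT": (72.12, 0.46),
    "SΔN-P": (64.95, 1.37),
    "S-PΔC": (62.99, 5.62),
    "SΔC-P": (46.82, 4.04),
    "SΔC-PΔC": (13.09, 2.87),
    "Spt16": (13.13, 0.35),
    "nucleosome": (9.23, 2.20),
}


def core_condition_summaries() -> list[ConditionSummary]:
    """The four-condition family, reconstructed as {m - s, m, m + s} triplets."""
    return [summary_condition(name, m, s) for name, (m, s) in CORE_CONDITIONS.items()]


def truncation_condition_summaries() -> list[ConditionSummary]:
    """The seven-condition truncation family, reconstructed as triplets."""
    return [summary_condition(name, m, s) for name, (m, s) in TRUNCATION_CONDITIONS.items()]
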
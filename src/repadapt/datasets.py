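"""Small bundled tables: the study's population phenotyping panel.

One row per population: proportion of assayed individuals surviving a
1.7 kg a.i./ha glyphosate application, and the study arm(s) the population
was used in (E = candidate-gene sequencing, P = population genomics).
"""

from .io_tables import PopulationPanel, PopulationRow

_ROWS = [
    # (population, survival, usage)
    ("SH4", 0.10, "EP"),
    ("CR", 0.21, "E"),
    ("IN12", 0.25, "E"),
    ("MA1", 0.25, "E"),
    ("SN", 0.50, "E"),
    ("RB", 0.18, "P"),
    ("HA", 0.15, "P"),
    ("FL", 0.20, "P"),
    ("MC", 0.67, "E"),
    ("CL1", 0.73, "E"),
    ("VA2", 0.82, "E"),
    ("WG", 0.83, "EP"),
    ("BI", 1.00, "EP"),
    ("DW", 1.00, "EP"),
    ("SPC", 0.71, "P"),
]


def study_panel() -> PopulationPanel:
    """The glyphosate-survival phenotyping panel used in the worked examples."""
    return PopulationPanel(
        [
            PopulationRow(population=p, survival=s, usage=frozenset(u))
            for p, s, u in _ROWS
        ]
    )
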
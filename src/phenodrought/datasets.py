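"""Reference validation tables from the original platform experiments.

Two drought protocols were screened on the platform: a soil-pot protocol
(60 pots sown, 10 failed germination, cohort n = 50) and a peat-pellet
protocol (48 pellets sown, 1 failed, cohort n = 47).  At every imaging
day the two automated classifiers (the color-class cluster cut and the
NIR Q3-index rule) were compared against manual wilting/dryness
inspection; the tables below record the published agreement percentages
and the printed goodness-of-fit p-values (2 significant figures).

These constants serve as frozen inputs for reproducing the published
statistics; nothing here is computed.
"""

from __future__ import annotations

FILL_CAPACITY_G = {"pot": 72.62, "pellet": 30.15}

POT_COHORT_N = 50  # 60 sown - 10 failed germination
PELLET_COHORT_N = 47  # 48 sown - 1 failed

POT_AGREEMENT = {
    "n": POT_COHORT_N,
    "das": [25, 28, 30, 32, 34, 35, 37, 40, 42, 43, 46, 53, 56],
    "cluster_pct": [64, 46, 52, 48, 44, 40, 68, 66, 66, 34, 98, 100, 76],
    "cluster_p": [
        "4.8e-02", "5.7e-01", "7.8e-01", "7.8e-01", "4.0e-01", "1.6e-01",
        "1.1e-02", "2.4e-02", "2.4e-02", "2.4e-02", "1.1e-11", "1.5e-12",
        "2.4e-04",
    ],
    "nir_pct": [100, 100, 98, 100, 100, 98, 94, 98, 98, 98, 94, 98, 98],
    "nir_p": [
        "1.5e-12", "1.5e-12", "1.1e-11", "1.5e-12", "1.5e-12", "1.1e-11",
        "4.9e-10", "1.1e-11", "1.1e-11", "1.1e-11", "4.9e-10", "1.1e-11",
        "1.1e-11",
    ],
}

PELLET_AGREEMENT = {
    "n": PELLET_COHORT_N,
    "das": [13, 16, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30],
    "cluster_pct": [83, 49, 85, 74, 70, 51, 79, 81, 85, 83, 81, 91, 91],
    "cluster_p": [
        "6.1e-06", "8.8e-01", "1.5e-06", "7.9e-04", "5.6e-03", "8.8e-01",
        "8.2e-05", "2.3e-05", "1.5e-06", "6.1e-06", "2.3e-05", "1.3e-08",
        "1.3e-08",
    ],
    "nir_pct": [100, 100, 100, 100, 100, 100, 96, 89, 87, 87, 94, 100, 100],
    "nir_p": [
        "7.1e-12", "7.1e-12", "7.1e-12", "7.1e-12", "7.1e-12", "7.1e-12",
        "3.6e-10", "6.8e-08", "3.3e-07", "3.3e-07", "2.2e-09", "7.1e-12",
        "7.1e-12",
    ],
}


def matches_from_percent(percent: float, total: int) -> int:
    """Match count behind a printed agreement percentage: round(pct*n/100)."""
    return int(round(percent * total / 100.0))


def agreement_cells(table: dict) -> list[tuple[str, int, int, int, str]]:
    """Flatten a reference table to (classifier, das, matches, n, printed_p)."""
    cells = []
    for classifier in ("cluster", "nir"):
        for das, pct, p in zip(table["das"], table[f"{classifier}_pct"], table[f"{classifier}_p"]):
            cells.append((classifier, das, matches_from_percent(pct, table["n"]), table["n"], p))
    return cells
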
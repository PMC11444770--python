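"""Frozen reference values for the statistics cross-check.

The samples are regenerated deterministically by the recipe functions below;
the W/p and t/df/p values were computed once with an independent reference
implementation (R 4.3 ``shapiro.test`` / ``t.test(var.equal=TRUE)``) on
exactly these samples and frozen here.  Tests require agreement to 1e-6.
"""

from __future__ import annotations

import numpy as np


def shapiro_sample(i: int) -> np.ndarray:
    """Seeded sample i of 20: alternating normal and exponential draws."""
    rng = np.random.default_rng(77000 + i)
    n = 5 + (i % 12)
    return rng.normal(10, 2, n) if i % 2 else rng.exponential(3.0, n)


def ttest_pair(i: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded group pair i of 10 with a mean shift growing in i."""
    rng = np.random.default_rng(88000 + i)
    a = rng.normal(10, 2, 3 + (i % 4))
    b = rng.normal(10 + 0.5 * i, 2, 3 + ((i + 1) % 4))
    return a, b


# (W, p) from R shapiro.test on shapiro_sample(i)
SHAPIRO_REFERENCE = (
    (0.933376797057372, 0.619571837287969),
    (0.969378692828288, 0.888235079471709),
    (0.823315861868106, 0.0691027525418809),
    (0.975562187142592, 0.93772245162825),
    (0.805373158876828, 0.0235155274509398),
    (0.865686605843256, 0.0890086101956582),
    (0.902694144956021, 0.199346765174068),
    (0.958091615377096, 0.756279078700756),
    (0.902765569829183, 0.145941839384863),
    (0.947834426203572, 0.527618219310142),
    (0.742739659266074, 0.000740490298163839),
    (0.918575754515757, 0.160005892014987),
    (0.849042668888695, 0.191511442784002),
    (0.922681505191392, 0.524880488651109),
    (0.73783949030448, 0.00945377494221221),
    (0.932896088818982, 0.542801208048441),
    (0.886036548126159, 0.181573297859682),
    (0.92914149727843, 0.439501192103107),
    (0.964680356867665, 0.828369121820407),
    (0.962148833684238, 0.814013033959774),
)

# (t, df, p) from R t.test(a, b, var.equal=TRUE) on ttest_pair(i)
TTEST_REFERENCE = (
    (-0.548667368858739, 5, 0.606833400369068),
    (-1.33984752807742, 7, 0.222154846099505),
    (-0.0828507326861235, 9, 0.935783667666843),
    (-1.14972204929627, 7, 0.288018888625054),
    (-1.10667498545936, 5, 0.318815048491102),
    (-0.656705561147183, 7, 0.532357894898224),
    (-0.995620839221238, 9, 0.345447592099855),
    (-2.01995757299706, 7, 0.0831355307107168),
    (-1.93227382624597, 5, 0.111165870515311),
    (-1.94268527737622, 7, 0.0931658663822283),
)
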
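"""Published reference statistics for the Koch-septum model suite.

Mean (+- 1 s.d.) maximum principal stresses, in MPa, reported for
physical-scale finite-element models of the four-lobed Koch phragmocone
suite (iterations 1-3) under 1, 2 and 3 MPa external pressure, sampled on
the external shell wall and on the (middle) septum.  These printed values
are the input of the depth-equivalence worked example: ordinary
least-squares trend lines of the shell-wall means versus pressure give the
pressure at which a more complex model reaches the simpler model's stress.
"""

from __future__ import annotations

from .analysis import RegionStats

__all__ = [
    "KOCH_PRESSURES",
    "KOCH_SHELL_WALL_MEAN",
    "KOCH_SHELL_WALL_SD",
    "KOCH_SEPTUM_MEAN",
    "KOCH_SEPTUM_SD",
    "koch_shell_wall_stats",
    "koch_septum_stats",
]

KOCH_PRESSURES = (1.0, 2.0, 3.0)  # MPa

# rows: pressure 1, 2, 3 MPa; columns: Koch iterations 1, 2, 3
KOCH_SHELL_WALL_MEAN = {
    1.0: (21.91, 18.73, 17.75),
    2.0: (44.75, 39.88, 36.95),
    3.0: (66.18, 58.47, 55.70),
}
KOCH_SHELL_WALL_SD = {
    1.0: (15.7, 14.1, 12.7),
    2.0: (32.2, 29.7, 25.6),
    3.0: (47.3, 43.3, 38.3),
}
KOCH_SEPTUM_MEAN = {
    1.0: (6.32, 11.03, 17.10),
    2.0: (10.33, 20.34, 29.45),
    3.0: (15.88, 32.40, 47.40),
}
KOCH_SEPTUM_SD = {
    1.0: (7.33, 9.38, 9.81),
    2.0: (13.2, 19.1, 18.4),
    3.0: (20.73, 19.10, 27.82),
}


def _stats(mean_table, sd_table, iteration: int, region: str):
    col = iteration - 1
    out = []
    for p in KOCH_PRESSURES:
        mean = mean_table[p][col]
        sd = sd_table[p][col]
        out.append(
            RegionStats(
                region=region,
                pressure=p,
                mean_max_principal=mean,
                sd=sd,
                peak=mean + sd,  # peak not published; placeholder >= mean
                n_samples=0,
            )
        )
    return out


def koch_shell_wall_stats(iteration: int) -> list[RegionStats]:
    """Published shell-wall stress statistics for a Koch iteration (1-3)."""
    return _stats(KOCH_SHELL_WALL_MEAN, KOCH_SHELL_WALL_SD, iteration, "shell_wall")


def koch_septum_stats(iteration: int) -> list[RegionStats]:
    """Published septum stress statistics for a Koch iteration (1-3)."""
    return _stats(KOCH_SEPTUM_MEAN, KOCH_SEPTUM_SD, iteration, "septum")
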
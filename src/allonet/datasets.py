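"""Bundled reference data: published GLIC tilt-angle summary statistics.

Per-subunit radial/lateral tilt means and sample standard deviations
(degrees) of the pore-lining TM2 helices and extracellular-domain
leaflets of GLIC, from coarse-grained simulations of the free channel
and three ligand-bound conditions (propofol in the transmembrane site,
propofol in the extracellular ketamine site, and a generic nonpolar
particle in the transmembrane site). Bound-condition tables carry the
published Δ values (condition mean − free mean, one decimal).

These tables serve as worked-example inputs: recomputing Δs from the
means must reproduce the published Δs to rounding precision.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = ["glic_tilt_tables", "CONDITIONS", "ELEMENTS"]

CONDITIONS = ("free", "propofol_tm", "propofol_ec", "generic_tm")
ELEMENTS = ("tm2", "leaflet")

# columns: subunit, radial_mean, radial_std, lateral_mean, lateral_std
# bound tables add: radial_delta, lateral_delta (published, one decimal)
_TABLES = {
    ("free", "tm2"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std
A\t13.8\t1.5\t-3.3\t1.6
B\t10.6\t1.3\t-1.5\t1.3
C\t9.8\t1.4\t-4.9\t1.3
D\t10.5\t1.2\t-4.2\t1.4
E\t11.0\t1.3\t-5.5\t1.4
""",
    ("free", "leaflet"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std
A\t10.2\t1.5\t6.2\t2.1
B\t10.6\t1.3\t4.5\t2.2
C\t6.9\t1.3\t4.1\t2.0
D\t11.0\t1.8\t-1.8\t2.3
E\t13.4\t2.2\t0.2\t2.1
""",
    ("propofol_tm", "tm2"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std\tradial_delta\tlateral_delta
A\t12.9\t0.9\t-3.3\t1.2\t-1.0\t-0.0
B\t11.3\t0.9\t-5.2\t1.1\t0.7\t-3.6
C\t11.3\t1.0\t-6.2\t1.2\t1.4\t-1.3
D\t13.3\t1.1\t4.6\t1.3\t2.7\t8.7
E\t8.2\t1.0\t1.7\t1.1\t-2.9\t7.2
""",
    ("propofol_ec", "tm2"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std\tradial_delta\tlateral_delta
A\t12.5\t1.2\t-4.1\t1.4\t-1.3\t-0.8
B\t11.5\t1.0\t-0.2\t1.6\t0.9\t1.3
C\t15.3\t1.7\t1.1\t1.8\t5.5\t6.0
D\t11.0\t1.1\t-0.4\t1.4\t0.5\t3.8
E\t8.2\t1.2\t-4.9\t1.3\t-2.9\t0.6
""",
    ("generic_tm", "tm2"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std\tradial_delta\tlateral_delta
A\t12.3\t2.6\t-3.9\t3.5\t-1.5\t-0.7
B\t12.7\t1.8\t-6.9\t1.8\t2.1\t-5.4
C\t10.8\t2.0\t-8.1\t3.9\t1.0\t-3.2
D\t13.7\t1.5\t-5.3\t3.6\t3.2\t-1.1
E\t10.3\t1.8\t-2.9\t3.6\t-0.8\t2.6
""",
    ("propofol_tm", "leaflet"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std\tradial_delta\tlateral_delta
A\t7.7\t1.3\t1.2\t1.9\t-2.6\t-5.0
B\t8.4\t1.0\t-7.3\t1.7\t-2.2\t-11.8
C\t7.2\t0.9\t4.9\t1.9\t0.3\t0.7
D\t12.6\t1.2\t9.0\t1.7\t1.6\t10.7
E\t16.3\t1.9\t2.3\t2.0\t2.9\t2.2
""",
    ("propofol_ec", "leaflet"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std\tradial_delta\tlateral_delta
A\t8.1\t1.3\t1.5\t2.2\t-2.1\t-4.6
B\t11.9\t1.5\t4.0\t2.1\t1.3\t-0.5
C\t10.6\t2.0\t7.2\t2.3\t3.7\t3.1
D\t8.8\t1.6\t5.8\t2.3\t-2.2\t7.5
E\t10.3\t1.5\t-6.7\t2.6\t-3.1\t-6.8
""",
    ("generic_tm", "leaflet"): """\
subunit\tradial_mean\tradial_std\tlateral_mean\tlateral_std\tradial_delta\tlateral_delta
A\t4.7\t1.3\t6.1\t3.8\t-5.6\t-0.1
B\t13.4\t1.5\t-2.8\t4.5\t2.8\t-7.3
C\t11.3\t2.0\t-1.4\t4.3\t4.4\t-5.5
D\t7.2\t1.8\t6.3\t6.4\t-3.8\t8.1
E\t11.8\t2.3\t4.0\t5.1\t-1.6\t3.9
""",
}


def glic_tilt_tables() -> dict[tuple[str, str], pd.DataFrame]:
    """All tilt summary tables keyed by (condition, element)."""
    return {
        key: pd.read_csv(StringIO(text), sep="\t") for key, text in _TABLES.items()
    }
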
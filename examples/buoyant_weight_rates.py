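"""From buoyant weighings to a calcification rate.

Two seasonal buoyant weighings of one coral are converted to skeletal dry
mass via Archimedes' principle (seawater density from the weighing-bath
temperature and salinity), then to a net calcification rate normalised to
the tissue-covered calyx area from calliper geometry.
"""

from datetime import date

from coralvar import (
    GeometryRecord,
    WeighingRecord,
    calcification_rate,
    cone_surface_area,
    dry_mass_from_buoyant,
    relative_calcification,
)

w_start = WeighingRecord("F-n042", date(2016, 9, 15), 3.1200, 12.5, 32.1)
w_end = WeighingRecord("F-n042", date(2017, 1, 15), 3.1618, 14.2, 32.1)

m_start = dry_mass_from_buoyant(w_start)
m_end = dry_mass_from_buoyant(w_end)
print(f"dry mass start : {m_start:.4f} g")
print(f"dry mass end   : {m_end:.4f} g")

geometry = GeometryRecord(
    "F-n042", date(2017, 8, 15),
    oral_diameter=18.1, basal_diameter=10.0, height=25.0, tissue_fraction=0.85,
)
area = cone_surface_area(geometry)
print(f"calyx area     : {area:.2f} cm2 (cup approximation, inner + outer face)")

days = (w_end.date - w_start.date).days
g = calcification_rate(m_start, m_end, days, area)
g_rel = relative_calcification(m_start, m_end, days)
print(f"calcification  : {g:.3f} mg CaCO3 cm-2 d-1 over {days} d")
print(f"               : {g_rel:.3f} % d-1 (normalised to initial dry mass)")
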
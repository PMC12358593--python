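"""Convert a raw gravimetric weighing series into moisture-gain units.

Capsule masses are normalised by the skin (shell) mass fraction Mfs
because only the gelatin shell takes up water: Mgr% = 100*(m1-m0)/(m0*Mfs).
"""

from pathlib import Path
import tempfile

from capsorb import read_mass_series_csv, skin_mass_fraction

# Mfs from a 4-capsule weighing: mean shell mass / mean capsule mass
mfs = skin_mass_fraction(
    capsule_masses_g=[1.02, 0.98, 1.01, 0.99], skin_masses_g=[0.21, 0.19, 0.20, 0.20]
)
print(f"skin mass fraction Mfs = {mfs:.3f}")

csv = (
    f"# mfs: {mfs}\n# temperature_c: 25\n# rh_percent: 68\n"
    "time_h,mass_g\n0,10.00\n0.5,10.09\n1.0,10.13\n1.5,10.15\n2.0,10.16\n"
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "weighings.csv"
    path.write_text(csv)
    series = read_mass_series_csv(path)

print(f"condition: {series.condition[0]:.2f} K, {series.condition[1]:.0f}% RH")
for t, mgr in series.points:
    print(f"  t = {t:3.1f} h   Mgr = {mgr:5.2f} %")
print("\nMgr is the percent mass gain of the shell itself; it is the y-axis")
print("of every kinetic fit in this package.")
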
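"""Physical constants in the package's working units.

Lengths are Å, time fs, energy eV, cross sections Å².  Masses are
expressed in eV·fs²/Å² so that E_kin = ½ m v² comes out in eV when
v is in Å/fs.
"""

#: Coulomb constant k = e²/(4πε₀) in eV·Å per unit charge pair.
COULOMB_K = 14.3996

#: Speed of light in Å/fs.
C_LIGHT = 2998.0

#: Electron rest mass, m_e c² = 511 keV  →  511000 / 2998² eV·fs²/Å².
M_ELECTRON = 0.056856

#: One atomic mass unit (931.494 MeV/c²) in eV·fs²/Å².
AMU = 931.494e6 / C_LIGHT**2

#: Rydberg energy (eV), used by the binary-encounter-Bethe cross section.
RYDBERG = 13.6057

#: Bohr radius (Å).
BOHR = 0.529177

#: hc in keV·Å, for converting photon energy to wavelength.
HC_KEV_A = 12.39842

#: Classical electron radius squared (Å²) — the Thomson cross-section scale
#: per unit solid angle, used when converting reciprocal-space intensity in
#: Thomson units to expected photon counts on a detector pixel.
R_E_SQ = (2.8179403e-5) ** 2
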
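"""Physical constants and the unit chain used throughout the package.

Doses are reported per unit administered activity in mGy/mCi.  Monte Carlo
tallies come out in MeV per gram per decay; the conversion chain is fixed
here and nowhere else:

* 1 mCi = 3.7e7 decays/s, i.e. 2.22e9 decays per mCi-minute,
* 1 MeV/g = 1.602e-7 mGy.
"""

#: decays per second per millicurie
MCI_TO_BQ = 3.7e7

#: decays per (mCi * minute)
DECAYS_PER_MCI_MIN = MCI_TO_BQ * 60.0  # 2.22e9

#: mGy per (MeV/g)
MGY_PER_MEV_PER_G = 1.602e-7

#: electron rest energy, MeV
ELECTRON_REST_MEV = 0.51099895

#: photon energy cut-off, MeV; below this the photon's remaining energy is
#: deposited at its current voxel (secondary-electron ranges are sub-voxel)
PHOTON_CUTOFF_MEV = 0.010

#: energy range of the embedded elemental attenuation data, keV
ATTENUATION_EMIN_KEV = 10.0
ATTENUATION_EMAX_KEV = 160.0
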
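"""Physical constants used across the package (CODATA 2018).

Internal unit conventions:

* length: nm
* force: nN  (so spring constants are nN/nm and energies nN*nm = 1e-18 J)
* magnetic field: mT internally; gauss (1 mT = 10 G) at interfaces
* microwave frequency: GHz
"""

#: Planck constant, J s
PLANCK_H = 6.62607015e-34

#: Bohr magneton, J/T
BOHR_MAGNETON = 9.2740100783e-24

#: Boltzmann constant, J/K
BOLTZMANN_J = 1.380649e-23

#: Boltzmann constant in simulation energy units, nN nm / K (1 nN nm = 1e-18 J)
BOLTZMANN_NN_NM = BOLTZMANN_J * 1e18

#: Free-electron g-factor (magnitude)
ELECTRON_G = 2.00231930436256

#: Standard gravity, m/s^2.  9.8 (not 9.80665) so that a 350 g load converts
#: to 3.43 N exactly at the printed precision; 9.80665 gives 3.432 N which
#: rounds identically.
STANDARD_GRAVITY = 9.8

#: Gauss per millitesla
GAUSS_PER_MT = 10.0
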
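"""Derivation of the default respiratory cost of synthesis, E.

E is the moles of carbon respired per mole of carbon incorporated into
biomass.  The bookkeeping is in electron equivalents:

* Biomass is taken as C5H7O2N1P1/30, built with nitrate as the nitrogen
  source.  Oxidizing one mole of this biomass back to CO2 and NO3- would
  release 4 electrons per C (mean carbon oxidation state 0) plus 8
  electrons per N (N(-III) -> N(+V)): 20 + 8 = 28 e-eq per 5 mol C, i.e.
  5.6 e-eq must be invested per mole of biomass carbon.  Phosphate is
  incorporated without redox change and contributes nothing.
* The electron (energy) donor for biosynthesis is photosynthetically fixed
  carbohydrate, CH2O, worth 4 e-eq per mole C when respired to CO2.
* At energy-transfer efficiency eps, carrying 1 e-eq into biomass costs
  (1-eps)/eps e-eq respired through the donor.

Hence

    E = (e-eq per biomass C) * (1-eps)/eps / (e-eq per donor C)
      = 5.6 * (0.4/0.6) / 4 = 14/15 = 0.9333...

Run:  python scripts/derive_respiratory_cost.py
"""

from fractions import Fraction


def biomass_electron_equivalents_per_c(
    c: int = 5, h: int = 7, o: int = 2, n: int = 1
) -> Fraction:
    """e-eq released by full oxidation of CxHyOzNn (N as NO3-) per mol C."""
    # mean carbon oxidation state from charge balance (H +1, O -2, N -3 in
    # biomass); oxidation to CO2 (+4) gives 4 - state electrons per C
    n_ox_state = -3
    c_ox_state = Fraction(-(h * 1 + o * -2 + n * n_ox_state), c)
    electrons_c = c * (4 - c_ox_state)
    electrons_n = n * (5 - n_ox_state)  # nitrate N is +V
    return Fraction(electrons_c + electrons_n, c)


def respiratory_cost(eps: Fraction = Fraction(3, 5),
                     donor_eeq_per_c: int = 4) -> Fraction:
    """Mol CO2 respired per mol biomass C at transfer efficiency eps."""
    per_c = biomass_electron_equivalents_per_c()
    return per_c * (1 - eps) / eps / donor_eeq_per_c


if __name__ == "__main__":
    per_c = biomass_electron_equivalents_per_c()
    e = respiratory_cost()
    print(f"biomass e-eq per mol C : {per_c} = {float(per_c):.4f}")
    print(f"donor (CH2O) e-eq per C: 4")
    print(f"transfer efficiency    : 3/5")
    print(f"E = {e} = {float(e):.6f} mol C respired per mol C synthesized")
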
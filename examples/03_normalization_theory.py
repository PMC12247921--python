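"""Closed-form predictions of divisive normalization.

z_n = v_n / (sigma + sum v): the bundle value v_bar/(sigma+v_bar) is concave
in the summed item value, and the code's responsiveness sigma/(sigma+v1+v2)^2
shrinks as soon as a companion item is present — the attenuation that the
neural analyses look for on bundle trials.
"""

import bundleval as bv

sigma = 1.0
print(f"normalize_values([1, 1], sigma=1) = {bv.normalize_values([1, 1], sigma)}")
print(f"bundle value of (1,1): {bv.bundle_value_normalized([1, 1], sigma):.4f} "
      "(= 2/3, less than the 2.0 a linear code would give)")

print("\nconcavity: value at v_bar=2 vs midpoint of v_bar=1 and v_bar=3:")
mid = 0.5 * (bv.bundle_value_normalized([1], sigma)
             + bv.bundle_value_normalized([3], sigma))
print(f"  f(2) = {bv.bundle_value_normalized([2], sigma):.4f} > midpoint {mid:.4f}")
print(f"  second derivative at v_bar=1: "
      f"{bv.bundle_second_derivative(1.0, sigma):.3f} (< 0 everywhere)")

print("\nattenuation of responsiveness by a companion item:")
print(f"  single item (v2=0):  {bv.responsiveness(0.0, 0.0, sigma):.4f}")
print(f"  companion v2=1:      {bv.responsiveness(1.0, 0.0, sigma):.4f}")
print(f"  companion v2=4:      {bv.responsiveness(4.0, 0.0, sigma):.4f}")
print("  -> a value code built on these responses is weaker on bundle trials")
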
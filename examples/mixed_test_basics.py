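"""The mixed Student's t-test on a hand-sized example.

Builds the three score samples the test consumes — the target promoter's
raw score (`one`), the ortholog scores (`obs`) and background scores
(`bkg`) — and prints the statistic, degrees of freedom, p-value and the two
diagnostics.
"""

import orthoscan as osc

one = 2.0                     # target promoter raw score
obs = [0.0, 1.0, 2.0, 3.0, 4.0]   # ortholog raw scores (contains `one`)
bkg = [-4.0, -3.0, -2.0, -1.0, 0.0]  # background raw scores

t_prime, df = osc.mixed_t(one, obs, bkg)
res = osc.mixed_test(one, obs, bkg)

print(f"t'  = {t_prime:.4f}   (negative when the target outscores background)")
print(f"df  = {df:.4f}   (Welch-Satterthwaite)")
print(f"p   = {res.p:.4f}   (lower tail)")
print(f"CCV = {res.ccv:.4f}   (|mean obs| / RMS deviation of obs around one)")
print(f"SD  = {res.sd:.4f}   (relative excess of one over the background mean)")

# CCV rises as ortholog scores tighten around the target's score; with a
# decently sized background sample the p-value falls alongside
print("\nconservation sweep (tighter orthologs -> larger CCV, smaller p):")
bkg_big = [-2.0 + 1.5 * (k - 24.5) / 14.5 for k in range(50)]
for spread in (2.0, 1.0, 0.5):
    obs_c = [one + spread * u for u in (-1.0, -0.5, 0.0, 0.5, 1.0)]
    r = osc.mixed_test(one, obs_c, bkg_big)
    print(f"  spread {spread:4.1f}:  CCV = {r.ccv:6.3f}  p = {r.p:.4g}")
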
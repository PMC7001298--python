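"""The frequency-dependent selection model and its closed-form inversion.

Walks one generation of the deterministic dynamics forward from a rare-HI
population, then recovers the selection coefficient from the observed change.
"""

from nfds import estimate_s, fitness_pair, forward_delta_p

p, s_true = 0.2, 0.3846153846

fit = fitness_pair(p, s_true)
print(f"At p_I = {p} with s_I = {s_true:.4f}:")
print(f"  W_I  = {fit.w_I:.4f}  (rare HI is fitter)")
print(f"  W_II = {fit.w_II:.4f}")
print(f"  mean fitness = {fit.w_bar:.4f}")

dp = forward_delta_p(p, s_true)
print(f"  one-generation change dp_I = {dp:+.4f}  -> p_I = {p + dp:.4f}")

est = estimate_s(p, dp)
print(f"Inverting the observed change: s_I = {est.value:.6f}")
print("Positive s_I means the change points toward the 0.5 attractor,")
print("i.e. selection favors whichever haplotype is currently rare.")
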
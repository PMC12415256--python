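"""Is the pre-insight surprisal elevation more than label frequencies explain?

Builds a small synthetic corpus, then compares the observed pre/post
epoch contrasts against a time-permuted surrogate null: labels are
shuffled across each session's fixed timestamps, preserving event timing
and per-inscription interaction counts while destroying sequential
structure.
"""

from insightews import ContextConfig, SimConfig, generate_corpus, surrogate_null

sim = SimConfig(n_steps=800)
corpus = generate_corpus(n_sessions=6, n_symbols=15, sim=sim, master_seed=2)
res = surrogate_null(
    corpus.event_series(),
    corpus.insights(),
    ContextConfig(delta=40.0),
    w_pre=80.0,
    w_post=80.0,
    n_permutations=199,
    seed=0,
)

print(f"observed contrast pre-insight : {res.observed_contrast_pre:+.3f} bits")
print(f"observed contrast post-insight: {res.observed_contrast_post:+.3f} bits")
print(f"null mean (pre): {res.null_pre.mean():+.3f} bits")
print(f"p (pre)  = {res.p_pre:.3f}   p (post) = {res.p_post:.3f}   "
      f"[{res.n_permutations} permutations]")
print("\nA small p means the elevation around insights cannot be explained")
print("by which inscriptions were used or when — only by the *order* in")
print("which attention moved between them.")
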
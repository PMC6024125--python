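# Placeholder data-derived informative priors.
#
# The real informative priors come from a multi-site hierarchical model's
# predictive distributions and are distributed with the study's supplementary
# material, which is not bundled here.  These stand-in values are tuned so
# that pushing the three vital-rate priors through the growth-rate identity
# lambda = s_a + s_j * f / 2 gives a prior-only distribution with mean 1.08
# and 95% interval (0.76, 1.66).  Replace this file with the real prior set
# when it is available; the loader only requires these four blocks.
priors:
  logit_phi_a:            # annual adult survival, logit scale
    family: normal
    scale: logit
    par1: 1.0515
    par2: 0.3775
  logit_phi_j:            # juvenile survival (fledging -> adulthood), logit scale
    family: normal
    scale: logit
    par1: -1.6300
    par2: 0.5911
  alpha_f:                # log mean fledglings per female per year
    family: normal
    scale: log
    par1: 1.2822
    par2: 0.3736
  sigma_female:           # SD of the female random effect on log fecundity
    family: uniform
    scale: natural
    par1: 0.0
    par2: 1.0
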
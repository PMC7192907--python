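# Inter-unit path resistances for the five-unit oscillator (ohms).
#
# SYNTHETIC stand-in: the published circuit drawing that carries these
# values was not available as data, so the package ships a plausible
# transcription fixed once: excitatory and recurrent (back-synapse) paths
# at 20 ohm -- the scale of the stated R_input/R_out paths, strong enough
# that the positive-feedback chain modulates the measured unit's firing --
# and inhibitory drawing paths at 100 ohm, weak enough that a frequency
# mismatch confined to the negative-feedback branch does not by itself
# decide the dynamics.  Override any entry via NetworkConfig.couplings.
#
# Keys are "source-target" for excitatory paths (charge pushed from the
# source unit's output into the target's capacitor), "drawer-victim" for
# inhibitory drawing paths, and "Ni-Ni" for back synapses.
N3-N4: 20.0
N4-N5: 20.0
N5-N3: 20.0
N3-N1: 20.0
N1-N3: 100.0
N1-N2: 100.0
N2-N1: 100.0
N1-N1: 20.0
N2-N2: 20.0
N3-N3: 20.0
N4-N4: 20.0
N5-N5: 20.0
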
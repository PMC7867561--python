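model,free_energy
delusions,-5966
disorganization,-6012
hallucinations,-6016
total positive,-5961
blunted affect,-6045
social withdrawal,-6068
lack of spontaneity,-6043
total negative,-6040
null,-6155
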
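name,delta_formula,class,max_count,aliases
hydroxylation,O,oxidation,8,oxidation
methylation,CH2,alkylation,8,
hexosylation,C6H10O5,glycosylation,3,glucosylation;galactosylation;glucose-conjugation;galactose-conjugation
rhamnosylation,C6H10O4,glycosylation,3,rhamnose-conjugation
pentosylation,C5H8O4,glycosylation,3,apiosylation;arabinosylation;apiose-conjugation;arabinose-conjugation
glucuronylation,C6H8O6,glycosylation,3,glucuronide-conjugation
benzoylation,C7H4O,acylation,2,
phenylpropanoylation,C9H6O2,acylation,2,coumaroylation
butylation,C4H8,alkylation,8,
prenylation,C5H8,alkylation,8,
dihydroxyphenylpropanoid-conjugation,C9H6O3,conjugation,2,phenylpropanoid-conjugation
dihydroxyphenylpropanoic-acid-conjugation,C9H8O4,conjugation,2,
catechin-conjugation,C15H12O6,conjugation,2,procyanidin-extension
tetrahydroxyflavanol-conjugation,C15H12O5,conjugation,2,
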
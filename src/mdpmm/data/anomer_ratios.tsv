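# Experimental anomer populations in aqueous solution (alpha : beta)
# columns: sugar	alpha	beta
glucose	32	68
galactose	38	62
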
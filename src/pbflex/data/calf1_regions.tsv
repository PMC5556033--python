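# Default region annotation for the Calf-1 domain of the integrin alphaIIb leg
# (beta-sandwich, author residue numbers 603-743): ten connector loops with the
# published spans, and the nine beta-strands filling the intervals between them.
name	kind	start	end
loop1	loop	603	611
strand1	strand	612	619
loop2	loop	620	629
strand2	strand	630	639
loop3	loop	640	646
strand3	strand	647	652
loop4	loop	653	656
strand4	strand	657	664
loop5	loop	665	672
strand5	strand	673	677
loop6	loop	678	683
strand6	strand	684	689
loop7	loop	690	695
strand7	strand	696	707
loop8	loop	708	715
strand8	strand	716	724
loop9	loop	725	735
strand9	strand	736	741
loop10	loop	742	743
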
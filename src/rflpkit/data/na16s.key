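# key=na16s enzyme=DraI region=16S min_visible=40 tol=5
1 count>2 -> 2 | count==2 -> 3
2(1) band1>200 -> 4 | band1<200 -> 5
3(1) band1>400 -> H. leporispalustris | band1<300 -> H. chordeilis
4(2) band2~200 -> H. leporispalustris | band2~175 -> H. juxtakochi
5(2) band2~160 -> H. juxtakochi | band1~160 -> H. longicornis
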
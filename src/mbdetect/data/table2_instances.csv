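Instance,MRI Appearance,Thickness Genu (mm),Thickness Body (mm),Thickness Splenium (mm),Length (mm),Width Genu (mm),Width Body (mm),Width Splenium (mm),ADC (x10^-3 mm^2/s),Gadolinium Enhancement,Signal Uniformity,Cystic Degeneration,Necrosis or Atrophy
1,T2 Hyperintense,7,2.5,3.8,55,12,9,14,0.5,Mild Enhancement,Non-uniform,Small cysts present,Necrosis present
2,T1 Hypointense,6,2,3,58,13,10,15,0.7,Moderate Enhancement,Non-uniform,Medium cysts present,Atrophy present
3,T2 Hyperintense,7.5,3,4,60,11,8,13,0.55,No Enhancement,Uniform,No cysts,Necrosis present
4,T1 Hypointense,8,2.8,4.2,62,14,11,16,0.9,Variable Enhancement,Non-uniform,Large cysts present,Atrophy present
5,Mixed,6.5,2.2,3.5,57,13.5,9.5,14.5,0.6,Mild Enhancement,Non-uniform,Small cysts present,Necrosis present
6,T2 Hyperintense,5,1.5,2.5,50,10,7,11,0.4,Strong Enhancement,Non-uniform,Medium cysts present,Atrophy present
7,T1 Hypointense,7.2,2.9,3.7,59,12.5,10.5,15.5,0.65,No Enhancement,Uniform,No cysts,Necrosis present
8,Mixed,7.8,3.1,4.1,61,13,9,15,0.8,Moderate Enhancement,Non-uniform,Large cysts present,Atrophy present
9,T2 Hyperintense,5.5,2,3.2,52,11,8.5,12.5,0.5,Strong Enhancement,Non-uniform,Small cysts present,Necrosis present
10,T1 Hypointense,6.8,2.6,3.9,65,14,12,17,0.75,Variable Enhancement,Non-uniform,Medium cysts present,Atrophy present
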
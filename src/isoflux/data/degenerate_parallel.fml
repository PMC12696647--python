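<fluxml name="degenerate_parallel">
  <metabolitepools>
    <pool id="A" atoms="2"/>
    <pool id="B" atoms="2"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="A" cfg="ab"/><rproduct id="B" cfg="ab"/></reaction>
    <reaction id="v2"><reduct id="A" cfg="ab"/><rproduct id="B" cfg="ab"/></reaction>
    <reaction id="v3"><reduct id="B" cfg="ab"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v3 = 1; v1 &gt;= 0.02; v1 &lt;= 0.98; v2 &gt;= 0.02; v2 &lt;= 0.98</net>
  </constraints>
  <configuration id="stat">
    <input pool="A"><label cfg="10" purity="1.0"/></input>
    <measurement>
      <group id="gB" spec="B#M(1,2)" times="inf" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
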
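<fluxml name="linchain">
  <metabolitepools>
    <pool id="A" atoms="2"/>
    <pool id="B" atoms="2"/>
    <pool id="C" atoms="2"/>
  </metabolitepools>
  <reactionnetwork>
    <reaction id="v1"><reduct id="A" cfg="ab"/><rproduct id="B" cfg="ab"/></reaction>
    <reaction id="v2"><reduct id="B" cfg="ab"/><rproduct id="C" cfg="ab"/></reaction>
    <reaction id="v3"><reduct id="C" cfg="ab"/></reaction>
  </reactionnetwork>
  <constraints>
    <net>v1 &gt;= 0.1; v1 &lt;= 10</net>
  </constraints>
  <configuration id="stat">
    <input pool="A">
      <label cfg="11" purity="0.5"/>
      <label cfg="00" purity="0.5"/>
    </input>
    <measurement>
      <group id="gC" spec="C#M(1,2)" times="inf" sd="0.01"/>
    </measurement>
  </configuration>
  <configuration id="kin">
    <input pool="A">
      <label cfg="11" purity="0.5"/>
      <label cfg="00" purity="0.5"/>
    </input>
    <measurement>
      <group id="gCk" spec="C#M(1,2)" times="0.4 1 2 4" sd="0.01"/>
    </measurement>
  </configuration>
</fluxml>
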